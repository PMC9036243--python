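"""Dose handling, SUV conversion and trajectory simulation.

Immuno-PET studies report tissue uptake as the standardized uptake value
(SUV): tissue activity concentration divided by injected dose per body
weight.  For an antibody tracer with negligible isotope corrections this
reduces to a mass-concentration ratio — SUV = 1 means the tissue holds the
same antibody mass per kg as the whole body on average.  The model
predicts interstitial and plasma molar concentrations; a tissue region of
interest is modelled as a two-component signal,

    SUV_tissue = (f_isf * Ctot + f_vasc * C_p) * MW * 1e-6 / (dose_mg / BW_kg)

with interstitial volume fraction ``f_isf`` (default 0.2, the canonical
ISF fraction of tissue volume), vascular volume fraction ``f_vasc``
(default 0.05), tissue density 1 g/mL, and ``MW * 1e-6`` converting nM to
mg/L.  Plasma SUV uses ``f_isf = 0, f_vasc = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ContractError, InvalidParameterError
from .model import NetworkSpec, integrate_network, network_from_study
from .params import StudyParameterSet

__all__ = [
    "DoseSpec",
    "SUVOptions",
    "Trajectory",
    "GradientSummary",
    "simulate",
    "suv_from_concentration",
    "summarize_gradient",
]

IGG_MW = 1.5e5  # g/mol, nominal IgG molecular weight


@dataclass(frozen=True)
class DoseSpec:
    """An intravenous bolus of antibody protein.

    The bolus raises plasma concentration by ``amount_mg / (MW * V_p)``
    (in molar units) at the dose time.
    """

    amount_mg: float = 10.0
    molecular_weight: float = IGG_MW
    body_weight_kg: float = 70.0
    time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.amount_mg <= 0.0:
            raise InvalidParameterError(f"dose must be > 0 mg, got {self.amount_mg}")
        if self.molecular_weight <= 0.0 or self.body_weight_kg <= 0.0:
            raise InvalidParameterError("MW and body weight must be > 0")
        if self.time_h != 0.0:
            raise InvalidParameterError("only a t=0 bolus is supported")

    def plasma_concentration_nM(self, V_p: float) -> float:
        """Initial plasma concentration (nM) after the bolus."""
        # mg -> g -> mol -> nmol, diluted in V_p litres
        return self.amount_mg * 1e6 / (self.molecular_weight * V_p)


@dataclass(frozen=True)
class SUVOptions:
    """Tissue-composition fractions and per-study scale for SUV output."""

    f_isf: float = 0.2
    f_vasc: float = 0.05
    suv_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_isf <= 1.0) or not (0.0 <= self.f_vasc <= 1.0):
            raise InvalidParameterError("volume fractions must lie in [0, 1]")
        if self.suv_scale <= 0.0:
            raise InvalidParameterError("suv_scale must be > 0")


def suv_from_concentration(
    C_tissue_total: Union[float, np.ndarray],
    f_isf: float,
    C_plasma: Union[float, np.ndarray],
    f_vasc: float,
    dose: DoseSpec,
) -> Union[float, np.ndarray]:
    """Convert interstitial + vascular molar concentrations to SUV.

    ``C_tissue_total`` is the total (free + bound) antibody concentration
    in the interstitial fluid (nM); ``C_plasma`` the plasma concentration.
    Plasma SUV itself is obtained with ``f_isf=0, f_vasc=1``.
    """
    if not (0.0 <= f_isf <= 1.0) or not (0.0 <= f_vasc <= 1.0):
        raise InvalidParameterError("volume fractions must lie in [0, 1]")
    mass_conc = (f_isf * np.asarray(C_tissue_total, dtype=float)
                 + f_vasc * np.asarray(C_plasma, dtype=float)
                 ) * dose.molecular_weight * 1e-6  # mg/L
    denom = dose.amount_mg / dose.body_weight_kg  # mg/kg
    out = mass_conc / denom
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class Trajectory:
    """Simulated concentration and SUV time courses for one network."""

    times: np.ndarray
    conc: Dict[str, np.ndarray]  # tissue label -> total antibody conc (nM)
    suv: Dict[str, np.ndarray]
    study_id: str = ""
    dose: Optional[DoseSpec] = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for d in (self.conc, self.suv):
            for label, series in d.items():
                if len(series) != n:
                    raise ContractError(f"series {label!r} length mismatch")

    @property
    def tissues(self) -> List[str]:
        return list(self.conc)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with columns study_id, tissue, time_h, conc_nM, suv."""
        rows = []
        for tissue in self.conc:
            rows.append(pd.DataFrame({
                "study_id": self.study_id,
                "tissue": tissue,
                "time_h": self.times,
                "conc_nM": self.conc[tissue],
                "suv": self.suv[tissue],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class GradientSummary:
    """AUCs, peaks and the PT:TDLN exposure ratio of one trajectory.

    AUCs are on the interstitial concentration scale (nM·h); peaks are on
    the SUV scale.  ``gradient_ratio`` is ``None`` when the TDLN sees no
    antibody (undefined gradient).
    """

    auc_pt: float
    auc_tdln: float
    suv_peak: Dict[str, float]
    gradient_ratio: Optional[float]


def simulate(
    params: Union[StudyParameterSet, NetworkSpec],
    dose: Optional[DoseSpec] = None,
    times: Optional[Sequence[float]] = None,
    *,
    suv_options: SUVOptions = SUVOptions(),
    rtol: float = None,
    atol: float = None,
) -> Trajectory:
    """Simulate an IV bolus through the PT–TDLN network.

    Parameters
    ----------
    params
        A registered/edited study parameter set (single lesion) or an
        explicit multi-lesion :class:`~tdlnpk.model.NetworkSpec`.
    dose
        IV bolus; ``None`` means no antibody (target baseline run).
    times
        Output grid in hours (default: 0–336 h, hourly).

    Returns a :class:`Trajectory` holding, per tissue, the total antibody
    concentration (nM; plasma for the "plasma" label) and the SUV signal.
    Deterministic for fixed inputs.
    """
    if times is None:
        times = np.linspace(0.0, 336.0, 337)
    times = np.asarray(times, dtype=float)
    if times[0] < 0.0 or times[-1] > 2000.0:
        raise ContractError("output grid must lie within [0, 2000] h")

    if isinstance(params, StudyParameterSet):
        net = network_from_study(params)
        study_id = params.study_id
    else:
        net = params
        study_id = ""

    if dose is None:
        c0 = 0.0
        dose_for_suv = DoseSpec()  # nominal; SUV of an all-zero run is zero
    else:
        c0 = dose.plasma_concentration_nM(net.V_p)
        dose_for_suv = dose

    y0 = net.initial_state(C_p0=c0)
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol
    states = integrate_network(net, y0, times, **kwargs)

    conc: Dict[str, np.ndarray] = {}
    suv: Dict[str, np.ndarray] = {}
    C_p = states[:, 0]
    conc["plasma"] = C_p
    suv["plasma"] = suv_options.suv_scale * suv_from_concentration(
        0.0, 0.0, C_p, 1.0, dose_for_suv)

    labels = net.tissue_labels()[1:]  # lesion and node labels in state order
    col = 2  # skip C_p, C_tissue
    for label in labels:
        Ctot = states[:, col]
        conc[label] = Ctot
        suv[label] = suv_options.suv_scale * suv_from_concentration(
            Ctot, suv_options.f_isf, C_p, suv_options.f_vasc, dose_for_suv)
        col += 2
    return Trajectory(times=times, conc=conc, suv=suv,
                      study_id=study_id, dose=dose)


def summarize_gradient(
    traj: Trajectory,
    pt_label: str = "PT",
    tdln_label: str = "PT/TDLN",
) -> GradientSummary:
    """Trapezoidal concentration AUCs, SUV peaks and the PT:TDLN ratio.

    The gradient ratio is ``None`` (undefined) when the TDLN exposure is
    numerically zero — e.g. after isolating the node with ``L_aff = 0``.
    """
    for label in (pt_label, tdln_label):
        if label not in traj.suv:
            raise ContractError(
                f"trajectory has no tissue {label!r}; present: {traj.tissues}")
    auc_pt = float(np.trapezoid(traj.conc[pt_label], traj.times))
    auc_tdln = float(np.trapezoid(traj.conc[tdln_label], traj.times))
    peaks = {t: float(np.max(s)) for t, s in traj.suv.items()}
    ratio = auc_pt / auc_tdln if auc_tdln > 0.0 else None
    return GradientSummary(auc_pt=auc_pt, auc_tdln=auc_tdln,
                           suv_peak=peaks, gradient_ratio=ratio)
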