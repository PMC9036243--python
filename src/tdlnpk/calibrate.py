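"""Least-squares calibration of the model against SUV observations.

Observations are sparse immuno-PET SUV means (optionally with standard
deviations) in plasma, primary tumor and/or TDLN.  A chosen subset of
parameters is freed — vascular leakiness ``sigma_v``, plasma clearance
``clp``, target densities ``r01``/``r02``, transit shape ``dln``, and the
SUV nuisance parameters ``f_vasc``/``suv_scale`` — and estimated by
box-constrained trust-region-reflective least squares on the SUV scale,
with optional inverse-SD weighting and a small seeded Latin-hypercube
multistart to escape poor basins.  Parameters with high uncertainty
should stay fixed at their registry (literature) values.

Fits that land on a bound are flagged, and a finite-difference probe
reports parameters to which the objective is locally insensitive, so a
flat direction (e.g. node-side parameters fitted on plasma-only data)
surfaces as ``identifiable=False`` rather than a spurious point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ContractError, InvalidParameterError
from .params import StudyParameterSet
from .simulate import DoseSpec, SUVOptions, simulate

__all__ = [
    "SUVObservation",
    "FitSpec",
    "FitResult",
    "fit",
    "read_observations_csv",
    "write_observations_csv",
    "DEFAULT_BOUNDS",
]

CSV_COLUMNS = ["study_id", "tissue", "time_h", "suv", "sd"]
VALID_TISSUES = ("plasma", "PT", "TDLN", "metastasis")

# physically motivated default boxes per free parameter
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "sigma_v": (0.0, 1.0),
    "clp": (1e-4, 1.0),
    "r01": (0.0, 1e4),
    "r02": (0.0, 1e4),
    "dln": (1.0, 200.0),
    "kd": (1e-4, 1e3),
    "f_vasc": (0.0, 0.5),
    "suv_scale": (0.1, 10.0),
}

# fit parameter name -> StudyParameterSet.replace keyword (SUV nuisance
# parameters are handled separately)
_STUDY_PARAMS = {
    "sigma_v": "sigma_v_pt",
    "clp": "CL_p",
    "r01": "R01",
    "r02": "R02",
    "dln": "dln",
    "kd": "Kd",
}
_SUV_PARAMS = ("f_vasc", "suv_scale")

_TISSUE_TO_LABEL = {"plasma": "plasma", "PT": "PT", "TDLN": "PT/TDLN"}


@dataclass(frozen=True)
class SUVObservation:
    """One measured SUV point: tissue, time, mean and dispersion."""

    study_id: str
    tissue: str
    time_h: float
    suv: float
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise InvalidParameterError(
                f"tissue must be one of {VALID_TISSUES}, got {self.tissue!r}")
        if self.time_h < 0.0:
            raise InvalidParameterError(f"time must be >= 0, got {self.time_h}")
        if self.suv < 0.0:
            raise InvalidParameterError(f"SUV must be >= 0, got {self.suv}")
        if self.sd is not None and self.sd < 0.0:
            raise InvalidParameterError(f"SD must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class FitSpec:
    """Which parameters to free, their boxes, initials and weighting."""

    free: Tuple[str, ...] = ("sigma_v", "r01", "r02", "dln", "clp")
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    initials: Dict[str, float] = field(default_factory=dict)
    weighting: str = "inverse_sd"  # "unweighted" | "inverse_sd" | "inverse_prediction"
    n_starts: int = 5
    seed: int = 20220414
    rtol: float = 1e-8

    def __post_init__(self) -> None:
        if len(self.free) == 0:
            raise ContractError("no free parameters")
        known = set(_STUDY_PARAMS) | set(_SUV_PARAMS)
        for name in self.free:
            if name not in known:
                raise InvalidParameterError(
                    f"unknown fit parameter {name!r}; known: {sorted(known)}")
        if self.weighting not in ("unweighted", "inverse_sd", "inverse_prediction"):
            raise InvalidParameterError(f"unknown weighting {self.weighting!r}")
        if self.n_starts < 1:
            raise InvalidParameterError("n_starts must be >= 1")

    def bound(self, name: str) -> Tuple[float, float]:
        lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
        if not lo < hi:
            raise InvalidParameterError(f"empty bounds for {name!r}: ({lo}, {hi})")
        return lo, hi


@dataclass
class FitResult:
    """Point estimates plus the diagnostics needed to trust (or not) them."""

    estimates: Dict[str, float]
    objective: float  # weighted SSE at the estimates
    residuals: pd.DataFrame
    at_bounds: Dict[str, bool]
    identifiable: bool
    uninformative: Tuple[str, ...]
    converged: bool
    message: str
    n_evaluations: int
    start_objectives: Tuple[float, ...]


def read_observations_csv(path) -> List[SUVObservation]:
    """Read observations from CSV (header study_id,tissue,time_h,suv,sd)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ContractError(f"observation CSV missing columns {missing}")
    obs = []
    for row in df.itertuples(index=False):
        sd = getattr(row, "sd", None)
        if sd is not None and (isinstance(sd, float) and math.isnan(sd)):
            sd = None
        obs.append(SUVObservation(
            study_id=str(row.study_id), tissue=str(row.tissue),
            time_h=float(row.time_h), suv=float(row.suv),
            sd=None if sd is None else float(sd),
        ))
    return obs


def write_observations_csv(observations: Sequence[SUVObservation], path) -> None:
    df = pd.DataFrame([{
        "study_id": o.study_id, "tissue": o.tissue, "time_h": o.time_h,
        "suv": o.suv, "sd": "" if o.sd is None else o.sd,
    } for o in observations], columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def _apply_vector(base: StudyParameterSet, names: Sequence[str],
                  x: np.ndarray, suv_base: SUVOptions):
    study_kw, f_vasc, scale = {}, suv_base.f_vasc, suv_base.suv_scale
    for name, v in zip(names, x):
        if name in _STUDY_PARAMS:
            study_kw[_STUDY_PARAMS[name]] = float(v)
        elif name == "f_vasc":
            f_vasc = float(v)
        elif name == "suv_scale":
            scale = float(v)
    study = base.replace(**study_kw) if study_kw else base
    return study, SUVOptions(f_isf=suv_base.f_isf, f_vasc=f_vasc, suv_scale=scale)


def fit(
    observations: Sequence[SUVObservation],
    spec: FitSpec,
    base: StudyParameterSet,
    dose: DoseSpec = DoseSpec(),
    suv_options: SUVOptions = SUVOptions(),
) -> FitResult:
    """Box-constrained least squares of model SUV against observations.

    Deterministic for a fixed ``spec.seed``.  The returned objective is
    the weighted sum of squared SUV residuals at the estimates.
    """
    observations = list(observations)
    if len(observations) == 0:
        raise ContractError("no observations")
    for o in observations:
        if o.tissue == "metastasis":
            raise ContractError(
                "metastasis observations need a multi-lesion fit; "
                "single-study fit supports plasma/PT/TDLN")

    names = list(spec.free)
    lo = np.array([spec.bound(n)[0] for n in names])
    hi = np.array([spec.bound(n)[1] for n in names])

    # initials: user-specified, else the base parameterization, clipped in-box
    def base_value(name: str) -> float:
        if name in _STUDY_PARAMS:
            attr = _STUDY_PARAMS[name]
            for holder in (base.physiology, base.target, base.transit):
                if hasattr(holder, attr):
                    return float(getattr(holder, attr))
        if name == "f_vasc":
            return suv_options.f_vasc
        return suv_options.suv_scale

    x0 = np.array([spec.initials.get(n, base_value(n)) for n in names])
    span = hi - lo
    x0 = np.clip(x0, lo + 1e-12 * span, hi - 1e-12 * span)

    times = np.unique(np.concatenate(
        [[0.0], [o.time_h for o in observations]]))
    if len(times) < 2:
        times = np.array([0.0, max(1.0, times[-1] + 1.0)])
    t_index = {t: i for i, t in enumerate(times)}
    y_obs = np.array([o.suv for o in observations])
    # zero / near-zero SDs (noise-free fixtures) fall back to unit weight
    sds = np.array([o.sd if (o.sd is not None and o.sd > 1e-12) else np.nan
                    for o in observations])

    if spec.weighting == "inverse_sd":
        w = np.where(np.isnan(sds), 1.0, 1.0 / np.where(np.isnan(sds), 1.0, sds))
    else:
        w = np.ones_like(y_obs)

    def predict(x: np.ndarray) -> np.ndarray:
        study, opts = _apply_vector(base, names, x, suv_options)
        traj = simulate(study, dose, times, suv_options=opts, rtol=spec.rtol)
        out = np.empty(len(observations))
        for k, o in enumerate(observations):
            label = _TISSUE_TO_LABEL[o.tissue]
            out[k] = traj.suv[label][t_index[o.time_h]]
        return out

    def residuals_fn(x: np.ndarray) -> np.ndarray:
        pred = predict(x)
        if spec.weighting == "inverse_prediction":
            wk = 1.0 / np.maximum(np.abs(pred), 1e-8)
        else:
            wk = w
        return wk * (pred - y_obs)

    # seeded Latin-hypercube multistart over the box (finite boxes only)
    starts = [x0]
    if spec.n_starts > 1:
        rng = np.random.default_rng(spec.seed)
        n_extra = spec.n_starts - 1
        u = (rng.permuted(
            np.tile(np.arange(n_extra), (len(names), 1)).T, axis=0)
            + rng.uniform(size=(n_extra, len(names)))) / n_extra
        for row in u:
            starts.append(lo + row * span)

    nfev = 0
    best = None
    start_objectives = []
    for xs in starts:
        res = least_squares(residuals_fn, xs, bounds=(lo, hi), method="trf",
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        nfev += res.nfev
        sse = float(np.sum(res.fun ** 2))
        start_objectives.append(sse)
        if best is None or sse < best[0]:
            best = (sse, res)
    objective, res = best

    estimates = {n: float(v) for n, v in zip(names, res.x)}
    tol = 1e-6
    at_bounds = {
        n: bool(abs(res.x[i] - lo[i]) <= tol * max(span[i], 1.0)
                or abs(res.x[i] - hi[i]) <= tol * max(span[i], 1.0))
        for i, n in enumerate(names)
    }

    # identifiability probe: perturb each estimate by +/-20 % of its value
    # (or 20 % of the box for zero estimates) and look for objective motion
    uninformative = []
    for i, n in enumerate(names):
        probe_obj = []
        step = 0.2 * abs(res.x[i]) if res.x[i] != 0 else 0.2 * span[i]
        for sgn in (-1.0, 1.0):
            xp = res.x.copy()
            xp[i] = np.clip(xp[i] + sgn * step, lo[i], hi[i])
            if xp[i] == res.x[i]:
                continue
            probe_obj.append(float(np.sum(residuals_fn(xp) ** 2)))
        if probe_obj:
            move = max(abs(po - objective) for po in probe_obj)
            if move <= max(1e-9, 1e-6 * objective):
                uninformative.append(n)

    pred = predict(res.x)
    resid_table = pd.DataFrame({
        "tissue": [o.tissue for o in observations],
        "time_h": [o.time_h for o in observations],
        "observed": y_obs,
        "predicted": pred,
        "weight": (1.0 / np.maximum(np.abs(pred), 1e-8)
                   if spec.weighting == "inverse_prediction" else w),
        "residual": pred - y_obs,
    })

    return FitResult(
        estimates=estimates,
        objective=objective,
        residuals=resid_table,
        at_bounds=at_bounds,
        identifiable=len(uninformative) == 0,
        uninformative=tuple(uninformative),
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=nfev,
        start_objectives=tuple(start_objectives),
    )
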