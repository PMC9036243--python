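"""Clinical what-if transforms over the base PT–TDLN model.

Three scenario families, each a pure transform of a registered study:

* **Metastasis** — additional lesion chains share the plasma pool; each
  metastatic lesion takes the physiology of its organ of residence and its
  own target density, so organ location (``L_organ``, ``sigma_v``,
  ``dln``) and target burden (``R01``, ``R02``) shape per-lesion
  gradients.
* **Surgical resection** — the primary tumor is removed (``R01 = 0``,
  tumor bed persists) and surgery-induced lymphedema reduces local lymph
  flows (``L_organ``, ``L_aff``) by a given fraction.
* **Inflammation** — rapid tumor growth compresses intratumoral
  lymphatics (afferent flow toward 0) while increasing peritumoral
  drainage; the PT efflux splits across several TDLN branches in
  proportion to their afferent flows, each branch with its own
  tumor-metastatic status (``R02 > 0`` or ``= 0``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence, Union

from .errors import ContractError, InvalidParameterError
from .library import get_study
from .model import LesionChain, NetworkSpec, TDLNCompartment, network_from_study
from .params import StudyParameterSet, TargetParams, TransitParams

__all__ = [
    "TDLNBranch",
    "lesion_from_study",
    "build_metastasis_model",
    "apply_surgery",
    "apply_inflammation",
    "load_scenario",
]

# defaults for inflammation remodelling: peritumoral drainage increase and
# the residual flow of a compressed intratumoral branch
PERITUMORAL_MULTIPLIER = 2.0
INTRATUMORAL_MULTIPLIER = 0.01


@dataclass(frozen=True)
class TDLNBranch:
    """One draining branch in an inflammation-remodelled TDLN network."""

    label: str
    position: str  # "intratumoral" | "peritumoral"
    tumor_status: str = "negative"  # "positive" (R02 > 0) | "negative"
    l_aff_multiplier: Optional[float] = None  # None -> position default

    def __post_init__(self) -> None:
        if self.position not in ("intratumoral", "peritumoral"):
            raise InvalidParameterError(f"unknown position {self.position!r}")
        if self.tumor_status not in ("positive", "negative"):
            raise InvalidParameterError(f"unknown tumor_status {self.tumor_status!r}")
        if self.l_aff_multiplier is not None and self.l_aff_multiplier < 0.0:
            raise InvalidParameterError("l_aff_multiplier must be >= 0")

    @property
    def multiplier(self) -> float:
        if self.l_aff_multiplier is not None:
            return self.l_aff_multiplier
        return (INTRATUMORAL_MULTIPLIER if self.position == "intratumoral"
                else PERITUMORAL_MULTIPLIER)


def lesion_from_study(
    study: StudyParameterSet,
    label: str,
    *,
    role: str = "metastasis",
    R01: Optional[float] = None,
    R02: Optional[float] = None,
    dln: Optional[float] = None,
) -> LesionChain:
    """Build a lesion chain with the physiology of ``study``'s organ.

    A lung metastasis, for instance, takes the lung (NSCLC) row's vascular
    leakiness, lymph flow and interstitial volume, optionally overriding
    target densities and the transit shape factor.
    """
    p = study.physiology
    tg = study.target
    if R01 is not None or R02 is not None:
        # rebuild so the synthesis rates re-derive from the new baselines
        tg = TargetParams(
            R01=tg.R01 if R01 is None else R01,
            R02=tg.R02 if R02 is None else R02,
            Kd=tg.Kd, k_deg=tg.k_deg, k_int=tg.k_int,
        )
    tr = study.transit
    if dln is not None:
        tr = dc_replace(tr, dln=dln)
    return LesionChain(
        label=label, sigma_v=p.sigma_v_pt, L_organ=p.L_organ,
        V_isf=p.V_isf_pt, target=tg, transit=tr, role=role,
        tdlns=(TDLNCompartment(label="TDLN", R02=tg.R02, L_aff=p.L_aff,
                               L_eff=p.L_eff, V_isf=p.V_isf_tdln),),
    )


def build_metastasis_model(
    base: StudyParameterSet,
    metastases: Sequence[LesionChain],
    primary: Optional[LesionChain] = None,
) -> NetworkSpec:
    """Assemble a multi-lesion network sharing one plasma pool.

    ``base`` supplies the plasma/lumped-tissue physiology and, unless
    ``primary`` is given, the primary-tumor chain.  Every lesion-TDLN
    chain keeps its own vascular leakiness, lymph flow, transit shape
    factor and target densities.
    """
    if len(metastases) == 0:
        raise ContractError("need at least one metastatic lesion")
    single = network_from_study(base)
    pt = primary if primary is not None else single.lesions[0]
    lesions = (pt,) + tuple(metastases)
    labels = [l.label for l in lesions]
    if len(set(labels)) != len(labels):
        raise ContractError(f"duplicate lesion labels: {labels}")
    return dc_replace(single, lesions=lesions)


def apply_surgery(
    base: StudyParameterSet,
    lymph_reduction: float,
) -> StudyParameterSet:
    """Resect the primary tumor and impair local lymphatic drainage.

    Sets ``R01 = 0`` (the tumor bed compartment persists without target)
    and multiplies the local lymph flows ``L_organ`` and ``L_aff`` by
    ``1 - lymph_reduction``, modelling surgery-induced lymphedema.
    """
    if not (0.0 <= lymph_reduction < 1.0):
        raise InvalidParameterError(
            f"lymph_reduction must lie in [0, 1), got {lymph_reduction}")
    keep = 1.0 - lymph_reduction
    return base.replace(
        R01=0.0,
        L_organ=base.physiology.L_organ * keep,
        L_aff=base.physiology.L_aff * keep,
    )


def apply_inflammation(
    base: StudyParameterSet,
    branches: Sequence[TDLNBranch],
) -> NetworkSpec:
    """Split PT drainage across inflammation-remodelled TDLN branches.

    Each branch receives afferent flow ``L_aff * multiplier`` (compressed
    intratumoral branches default to 0.01x, peritumoral to 2x) and its own
    node compartment: tumor-positive branches keep the study's ``R02``,
    tumor-negative branches carry no target.
    """
    if len(branches) < 2:
        raise ContractError("inflammation scenario needs >= 2 TDLN branches")
    labels = [b.label for b in branches]
    if len(set(labels)) != len(labels):
        raise ContractError(f"duplicate branch labels: {labels}")
    if all(b.multiplier == 0.0 for b in branches):
        raise ContractError("all afferent multipliers are zero: no drainage network")
    p = base.physiology
    nodes = tuple(
        TDLNCompartment(
            label=b.label,
            R02=base.target.R02 if b.tumor_status == "positive" else 0.0,
            L_aff=p.L_aff * b.multiplier,
            L_eff=p.L_eff,
            V_isf=p.V_isf_tdln,
        )
        for b in branches
    )
    single = network_from_study(base)
    lesion = dc_replace(single.lesions[0], tdlns=nodes)
    return dc_replace(single, lesions=(lesion,))


def load_scenario(
    spec: Union[str, dict],
    base: StudyParameterSet,
) -> Union[StudyParameterSet, NetworkSpec]:
    """Build a scenario model from a JSON file path or a dict.

    Recognized forms::

        {"type": "surgery", "lymph_reduction": 0.5}
        {"type": "inflammation",
         "branches": [{"label": "intra", "position": "intratumoral",
                       "tumor_status": "positive", "l_aff_multiplier": 0.01}, ...]}
        {"type": "metastasis",
         "metastases": [{"label": "lung_met", "organ_study": "bevacizumab_nsclc",
                         "r01": 10.0, "r02": 2.5, "dln": 21}, ...]}
    """
    if isinstance(spec, str):
        with open(spec) as fh:
            spec = json.load(fh)
    kind = spec.get("type")
    if kind == "surgery":
        return apply_surgery(base, float(spec["lymph_reduction"]))
    if kind == "inflammation":
        branches = [
            TDLNBranch(
                label=b["label"], position=b["position"],
                tumor_status=b.get("tumor_status", "negative"),
                l_aff_multiplier=b.get("l_aff_multiplier"),
            )
            for b in spec["branches"]
        ]
        return apply_inflammation(base, branches)
    if kind == "metastasis":
        mets = [
            lesion_from_study(
                get_study(m["organ_study"]) if "organ_study" in m else base,
                label=m["label"],
                R01=m.get("r01"), R02=m.get("r02"), dln=m.get("dln"),
            )
            for m in spec["metastases"]
        ]
        return build_metastasis_model(base, mets)
    raise ContractError(f"unknown scenario type {kind!r}")
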