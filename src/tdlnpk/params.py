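"""Parameter containers for the antibody PT–TDLN distribution model.

The model tracks an IgG antibody from plasma through a lumped non-tumor
tissue compartment and into one or more organ-specific primary tumors (PT),
each draining through lymphatic vessels into its tumor-draining lymph node
(TDLN).  Transport is purely convective: a flow ``L`` crossing a barrier
with reflection coefficient ``sigma`` carries solute with effective
clearance ``(1 - sigma) * L``.  Target engagement in PT and TDLN follows
quasi-equilibrium mass-action binding with first-order target turnover and
complex internalization.

Units used throughout: concentrations in nM, volumes in L, flows and
clearances in L/h, rate constants in 1/h, time in h.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Optional

from .errors import InvalidParameterError

__all__ = [
    "PhysiologyParams",
    "TargetParams",
    "TransitParams",
    "StudyParameterSet",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class PhysiologyParams:
    """Organ-level flows, volumes and reflection coefficients.

    Attributes
    ----------
    sigma_v_pt : float
        Vascular reflection coefficient of the primary tumor; the fraction
        of antibody rejected during transcapillary convection, in [0, 1].
    L_organ : float
        Lymph flow feeding the PT interstitium (L/h); by convention 0.2 %
        of organ blood flow.
    V_isf_pt : float
        PT interstitial fluid volume (L), 20 % of tumor/organ volume.
    V_p : float
        Plasma volume (L).
    CL_p : float
        Non-specific antibody clearance from plasma (L/h).
    sigma_l : float
        Lymphatic reflection coefficient (shared by all lymphatic exits).
    L_aff, L_eff : float
        Afferent (PT -> TDLN) and efferent (TDLN -> plasma) lymph flows
        (L/h).  ``L_aff`` may be zero (compressed, non-functional
        lymphatics in an inflamed tumor).
    V_isf_tdln : float
        TDLN interstitial fluid volume (L), 20 % of an average node.
    sigma_v_tdln : float
        Vascular reflection coefficient of the TDLN.  Fixed at 1 in every
        base configuration: high endothelial venules make direct
        blood-to-node antibody convection negligible, so lymph is the only
        entry route.
    L_tissue, sigma_v_tissue, V_isf_tissue : float
        Lumped non-tumor tissue compartment: its lymph flow, vascular
        reflection coefficient and interstitial volume.
    """

    sigma_v_pt: float
    L_organ: float
    V_isf_pt: float
    V_p: float
    CL_p: float
    sigma_l: float = 0.2
    L_aff: float = 0.004
    L_eff: float = 0.004
    V_isf_tdln: float = 5.84e-5
    sigma_v_tdln: float = 1.0
    L_tissue: float = 0.12
    sigma_v_tissue: float = 0.95
    V_isf_tissue: float = 8.4

    def __post_init__(self) -> None:
        for name in ("sigma_v_pt", "sigma_v_tdln", "sigma_l", "sigma_v_tissue"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        for name in ("L_organ", "V_isf_pt", "V_p", "CL_p", "L_eff",
                     "V_isf_tdln", "L_tissue", "V_isf_tissue"):
            v = getattr(self, name)
            _require(v > 0.0, f"{name} must be strictly positive, got {v}")
        _require(self.L_aff >= 0.0, f"L_aff must be non-negative, got {self.L_aff}")


@dataclass(frozen=True)
class TargetParams:
    """Target turnover and antibody binding constants.

    ``R01`` and ``R02`` are baseline (pre-dose) target concentrations in
    the PT and TDLN interstitium.  Synthesis rates default to
    ``k_syn = k_deg * R0`` so that, with no antibody present, the baseline
    is a fixed point of the turnover equations.  They can be pinned
    explicitly (``k_syn_pt``, ``k_syn_tdln``) — used when perturbing
    ``k_deg`` one-at-a-time while holding synthesis at its reference
    value, as a local sensitivity sweep requires.
    """

    R01: float
    R02: float
    Kd: float
    k_deg: float = 0.01
    k_int: float = 0.01
    k_syn_pt: Optional[float] = None
    k_syn_tdln: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.R01 >= 0.0, f"R01 must be non-negative, got {self.R01}")
        _require(self.R02 >= 0.0, f"R02 must be non-negative, got {self.R02}")
        _require(self.Kd > 0.0, f"Kd must be strictly positive, got {self.Kd}")
        _require(self.k_deg >= 0.0, f"k_deg must be non-negative, got {self.k_deg}")
        _require(self.k_int >= 0.0, f"k_int must be non-negative, got {self.k_int}")
        if self.k_syn_pt is None:
            object.__setattr__(self, "k_syn_pt", self.k_deg * self.R01)
        if self.k_syn_tdln is None:
            object.__setattr__(self, "k_syn_tdln", self.k_deg * self.R02)
        _require(self.k_syn_pt >= 0.0, "k_syn_pt must be non-negative")
        _require(self.k_syn_tdln >= 0.0, "k_syn_tdln must be non-negative")


@dataclass(frozen=True)
class TransitParams:
    """FcRn-salvage survival along the PT -> TDLN lymphatic path.

    During lymphatic transit, antibody is pinocytosed by lymphatic
    endothelial cells; the FcRn-bound fraction is recycled intact and
    continues downstream while the unbound remainder is degraded.  ``dln``
    is an empirical, organ-specific shape factor: larger values attenuate
    the cumulative loss (shorter/denser effective path), so survival
    increases with ``dln`` and decreases with ``Kd_FcRn``.

    ``uptake_prob`` (per-event pinocytosis probability) and ``n_ref``
    (reference number of uptake events) parameterize the default
    "power_shape" survival strategy; see :mod:`tdlnpk.transit`.
    """

    dln: float
    Kd_FcRn: float
    FcRn_conc: float = 40000.0  # 40 uM endothelial FcRn
    uptake_prob: float = 0.1
    n_ref: float = 100.0
    strategy: str = "power_shape"

    def __post_init__(self) -> None:
        _require(self.dln > 0.0, f"dln must be strictly positive, got {self.dln}")
        _require(self.Kd_FcRn > 0.0,
                 f"Kd_FcRn must be strictly positive, got {self.Kd_FcRn}")
        _require(self.FcRn_conc > 0.0,
                 f"FcRn_conc must be strictly positive, got {self.FcRn_conc}")
        _require(0.0 <= self.uptake_prob < 1.0,
                 f"uptake_prob must lie in [0, 1), got {self.uptake_prob}")
        _require(self.n_ref > 0.0, f"n_ref must be strictly positive, got {self.n_ref}")


@dataclass(frozen=True)
class StudyParameterSet:
    """A complete, named parameterization of one antibody:tumor pair."""

    study_id: str
    antibody: str
    tumor: str
    physiology: PhysiologyParams
    target: TargetParams
    transit: TransitParams
    source: str = ""

    @property
    def CL_p(self) -> float:
        return self.physiology.CL_p

    def replace(self, **kwargs: Any) -> "StudyParameterSet":
        """Return a copy with nested fields replaced.

        Keyword names are resolved against the sub-dataclasses, e.g.
        ``replace(sigma_v_pt=0.9, R01=20.0, dln=30.0)``.
        """
        phys_kw, targ_kw, tran_kw, top_kw = {}, {}, {}, {}
        phys_fields = {f.name for f in dataclasses.fields(PhysiologyParams)}
        targ_fields = {f.name for f in dataclasses.fields(TargetParams)}
        tran_fields = {f.name for f in dataclasses.fields(TransitParams)}
        top_fields = {f.name for f in dataclasses.fields(StudyParameterSet)}
        for k, v in kwargs.items():
            if k in phys_fields:
                phys_kw[k] = v
            elif k in targ_fields:
                targ_kw[k] = v
            elif k in tran_fields:
                tran_kw[k] = v
            elif k in top_fields:
                top_kw[k] = v
            else:
                raise InvalidParameterError(f"unknown parameter {k!r}")
        out = self
        if phys_kw:
            out = dataclasses.replace(out, physiology=dataclasses.replace(out.physiology, **phys_kw))
        if targ_kw:
            # rebuild rather than dataclasses.replace: synthesis rates
            # re-derive from the baseline fixed point unless pinned here
            t = out.target
            new_target = TargetParams(
                R01=targ_kw.get("R01", t.R01),
                R02=targ_kw.get("R02", t.R02),
                Kd=targ_kw.get("Kd", t.Kd),
                k_deg=targ_kw.get("k_deg", t.k_deg),
                k_int=targ_kw.get("k_int", t.k_int),
                k_syn_pt=targ_kw.get("k_syn_pt"),
                k_syn_tdln=targ_kw.get("k_syn_tdln"),
            )
            out = dataclasses.replace(out, target=new_target)
        if tran_kw:
            out = dataclasses.replace(out, transit=dataclasses.replace(out.transit, **tran_kw))
        if top_kw:
            out = dataclasses.replace(out, **top_kw)
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None, **json_kwargs) -> str:
        """Serialize to JSON; write to ``path`` if given."""
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **json_kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyParameterSet":
        return cls(
            study_id=d["study_id"],
            antibody=d["antibody"],
            tumor=d["tumor"],
            physiology=PhysiologyParams(**d["physiology"]),
            target=TargetParams(**d["target"]),
            transit=TransitParams(**d["transit"]),
            source=d.get("source", ""),
        )

    @classmethod
    def from_json(cls, text_or_path: str) -> "StudyParameterSet":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)
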