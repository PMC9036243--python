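"""Registry of the eleven calibrated antibody:tumor parameterizations.

Each entry pairs an immuno-PET-imaged IgG antibody with the organ-specific
physiology of its primary tumor and the antibody/target constants obtained
by model calibration against published human biodistribution studies.
Values shared across all studies: lymphatic reflection coefficient
``sigma_l = 0.2``, afferent and efferent node lymph flows
``L_aff = L_eff = 0.004 L/h``, TDLN interstitial volume ``5.84e-5 L``
(20 % of an average node), endothelial FcRn 40 uM, target degradation and
complex internalization rates ``k_deg = k_int = 0.01 1/h``.

Derivation conventions: organ lymph flow is 0.2 % of organ blood flow;
interstitial fluid volume is 20 % of total organ/tissue volume.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .errors import InvalidParameterError, UnknownStudyError
from .params import PhysiologyParams, StudyParameterSet, TargetParams, TransitParams

__all__ = [
    "get_study",
    "study_ids",
    "all_studies",
    "derive_lymph_flow",
    "derive_isf_volume",
]

# rows: (study_id, antibody, tumor,
#        sigma_v, L_organ [L/h], V_isf_pt [L], V_p [L],
#        R01 [nM], R02 [nM], Kd [nM], Kd_FcRn [nM], dln, CL_p [L/h], source)
_ROWS: Tuple[tuple, ...] = (
    ("fresolimumab_gbm", "89Zr-fresolimumab", "glioblastoma",
     0.94, 0.05, 0.265, 5.0, 1.0, 1.0, 1.7, 2400.0, 19.0, 0.075,
     "den Hollander et al. 2015"),
    ("bevacizumab_nsclc", "89Zr-bevacizumab", "NSCLC",
     0.85, 0.012, 0.175, 5.0, 10.0, 10.0, 0.058, 2400.0, 21.0, 0.07,
     "Bahce et al. 2014"),
    ("bevacizumab_breast", "89Zr-bevacizumab", "breast",
     0.95, 0.008, 0.112, 5.0, 1.0, 1.5, 0.058, 2400.0, 20.0, 0.06,
     "Gaykema et al. 2013"),
    ("bevacizumab_renal", "89Zr-bevacizumab", "renal cell carcinoma",
     0.97, 0.082, 0.060, 5.0, 10.0, 2.5, 0.058, 2400.0, 21.0, 0.042,
     "Oosting et al. 2015"),
    ("trastuzumab_breast", "64Cu-DOTA-trastuzumab", "breast",
     0.65, 0.008, 0.112, 5.0, 100.0, 100.0, 5.0, 774.0, 61.0, 0.063,
     "Tamura et al. 2013"),
    ("trastuzumab_esophagogastric", "89Zr-trastuzumab", "esophagogastric",
     0.95, 0.007, 0.005, 7.0, 30.0, 30.0, 5.0, 774.0, 63.0, 0.0288,
     "O'Donoghue et al. 2018"),
    ("mmot0530a_pancreatic", "89Zr-MMOT0530A", "pancreatic",
     0.87, 0.004, 0.029, 5.0, 1000.0, 1000.0, 0.5, 2400.0, 21.0, 0.033,
     "Lamberts et al. 2016"),
    ("mmot0530a_ovarian", "89Zr-MMOT0530A", "ovarian",
     0.95, 0.004, 0.001, 5.0, 24.0, 24.0, 0.5, 2400.0, 24.0, 0.033,
     "Lamberts et al. 2016"),
    ("atezolizumab_nsclc", "89Zr-atezolizumab", "NSCLC",
     0.80, 0.012, 0.175, 5.0, 7.0, 7.0, 0.43, 2400.0, 21.0, 0.0083,
     "Bensch et al. 2018"),
    ("atezolizumab_breast", "89Zr-atezolizumab", "breast",
     0.90, 0.008, 0.112, 5.0, 1.0, 2.5, 0.43, 2400.0, 20.0, 0.0083,
     "Bensch et al. 2018"),
    ("atezolizumab_bladder", "89Zr-atezolizumab", "bladder",
     0.86, 0.001, 0.0084, 5.0, 11.0, 11.0, 0.43, 2400.0, 24.0, 0.0083,
     "Bensch et al. 2018"),
)


def _build_registry() -> Dict[str, StudyParameterSet]:
    registry: Dict[str, StudyParameterSet] = {}
    for (sid, ab, tumor, sigma_v, l_organ, v_isf, v_p,
         r01, r02, kd, kd_fcrn, dln, cl_p, source) in _ROWS:
        registry[sid] = StudyParameterSet(
            study_id=sid,
            antibody=ab,
            tumor=tumor,
            physiology=PhysiologyParams(
                sigma_v_pt=sigma_v, L_organ=l_organ, V_isf_pt=v_isf,
                V_p=v_p, CL_p=cl_p,
            ),
            target=TargetParams(R01=r01, R02=r02, Kd=kd),
            transit=TransitParams(dln=dln, Kd_FcRn=kd_fcrn),
            source=source,
        )
    return registry


_REGISTRY = _build_registry()


def study_ids() -> Tuple[str, ...]:
    """Identifiers of all registered antibody:tumor pairs, in table order."""
    return tuple(row[0] for row in _ROWS)


def get_study(study_id: str) -> StudyParameterSet:
    """Return the immutable parameter set for one registered pair.

    Raises
    ------
    UnknownStudyError
        If ``study_id`` is not registered; the message lists valid ids.
    """
    try:
        return _REGISTRY[study_id]
    except KeyError:
        raise UnknownStudyError(
            f"unknown study {study_id!r}; valid ids: {', '.join(study_ids())}"
        ) from None


def all_studies() -> Tuple[StudyParameterSet, ...]:
    return tuple(_REGISTRY[sid] for sid in study_ids())


def derive_lymph_flow(organ_blood_flow: float) -> float:
    """Organ lymph flow (L/h) as 0.2 % of organ blood flow (L/h)."""
    if organ_blood_flow <= 0.0:
        raise InvalidParameterError(
            f"organ blood flow must be > 0, got {organ_blood_flow}")
    return 0.002 * organ_blood_flow


def derive_isf_volume(total_volume: float, fraction: float = 0.20) -> float:
    """Interstitial fluid volume (L) as a fraction of total organ volume."""
    if total_volume <= 0.0:
        raise InvalidParameterError(f"volume must be > 0, got {total_volume}")
    if not (0.0 < fraction < 1.0):
        raise InvalidParameterError(f"fraction must lie in (0, 1), got {fraction}")
    return fraction * total_volume
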