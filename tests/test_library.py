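"""Registry snapshot and the shared derivation rules."""

import pytest

import tdlnpk as tk
from tdlnpk import InvalidParameterError, UnknownStudyError

# full snapshot: (sigma_v, L_organ, V_isf_pt, V_p, R01, R02, Kd, Kd_FcRn,
# dln, CL_p) per study
SNAPSHOT = {
    "fresolimumab_gbm":            (0.94, 0.05, 0.265, 5.0, 1, 1, 1.7, 2400, 19, 0.075),
    "bevacizumab_nsclc":           (0.85, 0.012, 0.175, 5.0, 10, 10, 0.058, 2400, 21, 0.07),
    "bevacizumab_breast":          (0.95, 0.008, 0.112, 5.0, 1, 1.5, 0.058, 2400, 20, 0.06),
    "bevacizumab_renal":           (0.97, 0.082, 0.060, 5.0, 10, 2.5, 0.058, 2400, 21, 0.042),
    "trastuzumab_breast":          (0.65, 0.008, 0.112, 5.0, 100, 100, 5, 774, 61, 0.063),
    "trastuzumab_esophagogastric": (0.95, 0.007, 0.005, 7.0, 30, 30, 5, 774, 63, 0.0288),
    "mmot0530a_pancreatic":        (0.87, 0.004, 0.029, 5.0, 1000, 1000, 0.5, 2400, 21, 0.033),
    "mmot0530a_ovarian":           (0.95, 0.004, 0.001, 5.0, 24, 24, 0.5, 2400, 24, 0.033),
    "atezolizumab_nsclc":          (0.80, 0.012, 0.175, 5.0, 7, 7, 0.43, 2400, 21, 0.0083),
    "atezolizumab_breast":         (0.90, 0.008, 0.112, 5.0, 1, 2.5, 0.43, 2400, 20, 0.0083),
    "atezolizumab_bladder":        (0.86, 0.001, 0.0084, 5.0, 11, 11, 0.43, 2400, 24, 0.0083),
}


def test_registry_has_exactly_eleven_studies():
    assert len(tk.study_ids()) == 11
    assert set(tk.study_ids()) == set(SNAPSHOT)


@pytest.mark.parametrize("study_id", sorted(SNAPSHOT))
def test_registry_snapshot(study_id):
    s = tk.get_study(study_id)
    sigma_v, l_organ, v_isf, v_p, r01, r02, kd, kd_fcrn, dln, cl_p = SNAPSHOT[study_id]
    assert s.physiology.sigma_v_pt == sigma_v
    assert s.physiology.L_organ == l_organ
    assert s.physiology.V_isf_pt == v_isf
    assert s.physiology.V_p == v_p
    assert s.target.R01 == r01
    assert s.target.R02 == r02
    assert s.target.Kd == kd
    assert s.transit.Kd_FcRn == kd_fcrn
    assert s.transit.dln == dln
    assert s.physiology.CL_p == cl_p


def test_shared_constants_across_all_studies():
    for s in tk.all_studies():
        p = s.physiology
        assert p.sigma_l == 0.2
        assert p.L_aff == 0.004 and p.L_eff == 0.004
        assert p.V_isf_tdln == 5.84e-5
        assert p.sigma_v_tdln == 1.0
        assert s.target.k_deg == 0.01 and s.target.k_int == 0.01
        assert s.transit.FcRn_conc == 40000.0


def test_unknown_study_lists_valid_ids():
    with pytest.raises(UnknownStudyError, match="bevacizumab_renal"):
        tk.get_study("nivolumab_melanoma")


def test_lymph_flow_rule():
    assert tk.derive_lymph_flow(41.0) == pytest.approx(0.082)
    assert tk.derive_lymph_flow(6.0) == pytest.approx(0.012)
    with pytest.raises(InvalidParameterError):
        tk.derive_lymph_flow(0.0)


def test_isf_volume_rule():
    assert tk.derive_isf_volume(0.000292) == pytest.approx(5.84e-5)
    assert tk.derive_isf_volume(0.30) == pytest.approx(0.060)
    assert tk.derive_isf_volume(1.0, fraction=0.5) == 0.5
    with pytest.raises(InvalidParameterError):
        tk.derive_isf_volume(1.0, fraction=1.5)
    with pytest.raises(InvalidParameterError):
        tk.derive_isf_volume(-1.0)


def test_json_round_trip(renal, tmp_path):
    path = tmp_path / "renal.json"
    renal.to_json(path)
    back = tk.StudyParameterSet.from_json(str(path))
    assert back == renal


def test_replace_rederives_target_synthesis(renal):
    cut = renal.replace(R01=0.0)
    assert cut.target.k_syn_pt == 0.0
    pinned = renal.replace(k_deg=1.0, k_syn_pt=renal.target.k_syn_pt)
    assert pinned.target.k_syn_pt == renal.target.k_syn_pt
    with pytest.raises(InvalidParameterError):
        renal.replace(no_such_parameter=1.0)
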