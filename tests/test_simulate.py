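"""Dosing, SUV conversion, trajectory output and gradient summaries."""

import numpy as np
import pytest

import tdlnpk as tk
from tdlnpk import ContractError, DoseSpec, InvalidParameterError, SUVOptions


def test_bolus_concentration_conversion():
    # 10 mg IgG (150 kDa) into 5 L plasma -> 13.33 nM
    assert DoseSpec(10.0).plasma_concentration_nM(5.0) == pytest.approx(13.333, abs=1e-3)


def test_dose_must_be_positive():
    with pytest.raises(InvalidParameterError):
        DoseSpec(amount_mg=0.0)


def test_plasma_suv_definitional_identity():
    # whole-body-uniform concentration has SUV exactly 1
    dose = DoseSpec(10.0, body_weight_kg=70.0)
    c_uniform = 10.0 / 70.0 / (1.5e5 * 1e-6)  # mg/L -> nM
    assert tk.suv_from_concentration(0.0, 0.0, c_uniform, 1.0, dose) == \
        pytest.approx(1.0)


def test_tissue_suv_arithmetic():
    # 10 mg in 1 L at 150 kDa = 66.67 nM; f_isf 0.2 -> SUV 14 at 10mg/70kg
    dose = DoseSpec(10.0, body_weight_kg=70.0)
    c = 10.0 / (1.5e5) * 1e6  # nM in 1 L
    assert tk.suv_from_concentration(c, 0.2, 0.0, 0.0, dose) == pytest.approx(14.0)
    assert tk.suv_from_concentration(0.0, 0.2, 0.0, 0.05, dose) == 0.0


def test_zero_dose_gives_zero_suv_everywhere(renal):
    traj = tk.simulate(renal, dose=None, times=np.linspace(0, 100, 11))
    for tissue in traj.tissues:
        assert np.all(traj.suv[tissue] == 0.0)


def test_pt_exceeds_tdln_at_all_times(renal_traj):
    # renal PT outcompetes its node: higher target density and transit loss
    pt, ln = renal_traj.suv["PT"], renal_traj.suv["PT/TDLN"]
    assert np.all(pt[1:] > ln[1:])


def test_suv_dose_invariant_when_linear(renal, week_grid):
    s = renal.replace(R01=0.0, R02=0.0)
    t1 = tk.simulate(s, DoseSpec(10.0), week_grid)
    t2 = tk.simulate(s, DoseSpec(20.0), week_grid)
    for tissue in t1.tissues:
        np.testing.assert_allclose(t1.suv[tissue], t2.suv[tissue], rtol=1e-6)


def test_suv_non_increasing_in_dose_with_target(renal, week_grid):
    # saturable target-mediated uptake: higher dose, lower normalized uptake
    t1 = tk.simulate(renal, DoseSpec(10.0), week_grid)
    t2 = tk.simulate(renal, DoseSpec(20.0), week_grid)
    assert np.all(t2.suv["PT"][1:] <= t1.suv["PT"][1:] * (1 + 1e-9))
    assert t2.suv["PT"].max() < t1.suv["PT"].max()


def test_auc_grid_invariance(renal, dose):
    fine = tk.simulate(renal, dose, np.linspace(0, 336, 337))
    coarse = tk.simulate(renal, dose, np.linspace(0, 336, 169))
    auc_fine = np.trapezoid(fine.conc["PT"], fine.times)
    auc_coarse = np.trapezoid(coarse.conc["PT"], coarse.times)
    assert abs(auc_fine - auc_coarse) / auc_fine < 1e-3


def test_renal_peak_dominates_brain_and_lung(dose, week_grid):
    peaks = {}
    for sid in ("bevacizumab_renal", "fresolimumab_gbm",
                "bevacizumab_nsclc", "atezolizumab_nsclc"):
        peaks[sid] = tk.simulate(tk.get_study(sid), dose, week_grid).suv["PT"].max()
    assert peaks["bevacizumab_renal"] > peaks["fresolimumab_gbm"]
    assert peaks["bevacizumab_renal"] > peaks["bevacizumab_nsclc"]
    assert peaks["bevacizumab_renal"] > peaks["atezolizumab_nsclc"]


def test_renal_has_steepest_pt_tdln_gradient(dose, week_grid):
    # highest tumor-to-node target ratio (R01/R02 = 4) -> steepest gradient
    ratios = {}
    for sid in tk.study_ids():
        traj = tk.simulate(tk.get_study(sid), dose, week_grid)
        ratios[sid] = tk.summarize_gradient(traj).gradient_ratio
    assert max(ratios, key=ratios.get) == "bevacizumab_renal"


def test_gradient_summary_identity_and_isolation(renal, dose, week_grid):
    traj = tk.simulate(renal, dose, week_grid)
    g = tk.summarize_gradient(traj)
    assert g.auc_pt > g.auc_tdln > 0
    assert g.gradient_ratio == pytest.approx(g.auc_pt / g.auc_tdln)

    # identical series -> ratio exactly 1
    traj.conc["PT/TDLN"] = traj.conc["PT"].copy()
    assert tk.summarize_gradient(traj).gradient_ratio == pytest.approx(1.0)

    # isolated node -> undefined ratio, flagged as None
    cut = tk.simulate(renal.replace(L_aff=0.0), dose, week_grid)
    assert tk.summarize_gradient(cut).gradient_ratio is None

    with pytest.raises(ContractError):
        tk.summarize_gradient(traj, tdln_label="nonexistent")


def test_trajectory_tidy_export(renal_traj, tmp_path):
    df = renal_traj.to_frame()
    assert list(df.columns) == ["study_id", "tissue", "time_h", "conc_nM", "suv"]
    assert set(df["tissue"]) == {"plasma", "PT", "PT/TDLN"}
    assert (df["study_id"] == "bevacizumab_renal").all()
    path = tmp_path / "traj.csv"
    renal_traj.to_csv(path)
    assert path.exists() and path.stat().st_size > 0


def test_simulation_grid_contract(renal, dose):
    with pytest.raises(ContractError):
        tk.simulate(renal, dose, np.linspace(0, 3000, 10))
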