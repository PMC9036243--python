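"""Metastasis, surgery and inflammation transforms and their orderings."""

import json

import numpy as np
import pytest

import tdlnpk as tk
from tdlnpk import ContractError, InvalidParameterError, TDLNBranch
from tdlnpk.model import integrate_network, network_from_study, quasi_equilibrium_bind


def auc(traj, tissue):
    return float(np.trapezoid(traj.conc[tissue], traj.times))


# ---------------------------------------------------------------- surgery
def test_surgery_zeroes_target_and_scales_flows(renal):
    s = tk.apply_surgery(renal, 0.5)
    assert s.target.R01 == 0.0 and s.target.k_syn_pt == 0.0
    assert s.physiology.L_organ == pytest.approx(renal.physiology.L_organ / 2)
    assert s.physiology.L_aff == pytest.approx(renal.physiology.L_aff / 2)
    s0 = tk.apply_surgery(renal, 0.0)
    assert s0.target.R01 == 0.0
    assert s0.physiology.L_organ == renal.physiology.L_organ
    with pytest.raises(InvalidParameterError):
        tk.apply_surgery(renal, 1.0)
    with pytest.raises(InvalidParameterError):
        tk.apply_surgery(renal, -0.1)


def test_surgery_monotonically_starves_the_residual_node(renal, dose, week_grid):
    aucs = [auc(tk.simulate(tk.apply_surgery(renal, r), dose, week_grid),
                "PT/TDLN")
            for r in (0.0, 0.3, 0.5, 0.8, 0.9)]
    assert all(a > b for a, b in zip(aucs, aucs[1:]))


# ------------------------------------------------------------- metastasis
def test_two_identical_lesions_have_identical_trajectories(renal, dose, week_grid):
    m1 = tk.lesion_from_study(renal, "met1")
    m2 = tk.lesion_from_study(renal, "met2")
    net = tk.build_metastasis_model(renal, [m1, m2])
    traj = tk.simulate(net, dose, week_grid)
    np.testing.assert_allclose(traj.conc["met1"], traj.conc["met2"],
                               rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(traj.conc["met1/TDLN"], traj.conc["met2/TDLN"],
                               rtol=1e-9, atol=1e-12)


def test_high_met_target_density_starves_its_node(renal, dose, week_grid):
    lung = tk.get_study("bevacizumab_nsclc")
    m_eq = tk.lesion_from_study(lung, "met", R01=2.5, R02=2.5)
    m_hi = tk.lesion_from_study(lung, "met", R01=25.0, R02=2.5)
    a_eq = auc(tk.simulate(tk.build_metastasis_model(renal, [m_eq]), dose,
                           week_grid), "met/TDLN")
    a_hi = auc(tk.simulate(tk.build_metastasis_model(renal, [m_hi]), dose,
                           week_grid), "met/TDLN")
    assert a_hi < a_eq


def test_target_free_met_reduces_to_linear_compartment(renal, dose, week_grid):
    met = tk.lesion_from_study(renal, "met", R01=0.0, R02=0.0)
    net = tk.build_metastasis_model(renal, [met])
    states = integrate_network(net, net.initial_state(
        dose.plasma_concentration_nM(net.V_p)), week_grid)
    # with zero target the lesion's Rtot stays zero: pure convection
    labels = net.state_labels()
    assert np.max(np.abs(states[:, labels.index("Rtot[met]")])) <= 1e-12
    assert np.all(states[:, labels.index("Ctot[met]")] >= -1e-12)


def test_removing_metastases_recovers_base_exactly(renal, dose, week_grid):
    base_traj = tk.simulate(renal, dose, week_grid)
    net = network_from_study(renal)
    rebuilt = tk.simulate(net, dose, week_grid)
    np.testing.assert_array_equal(base_traj.conc["PT"], rebuilt.conc["PT"])


def test_duplicate_lesion_labels_rejected(renal):
    m = tk.lesion_from_study(renal, "PT")  # collides with the primary
    with pytest.raises(ContractError):
        tk.build_metastasis_model(renal, [m])
    with pytest.raises(ContractError):
        tk.build_metastasis_model(renal, [])


# ----------------------------------------------------------- inflammation
def test_compressed_intratumoral_branch_is_underexposed(renal, dose, week_grid):
    net = tk.apply_inflammation(renal, [
        TDLNBranch("intra", "intratumoral", "positive", 0.01),
        TDLNBranch("peri", "peritumoral", "positive", 2.0),
    ])
    traj = tk.simulate(net, dose, week_grid)
    assert np.all(traj.conc["PT/peri"][1:] > traj.conc["PT/intra"][1:])
    assert np.all(traj.suv["PT/peri"][1:] >= traj.suv["PT/intra"][1:])


def test_symmetric_branches_are_identical(renal, dose, week_grid):
    net = tk.apply_inflammation(renal, [
        TDLNBranch("a", "peritumoral", "positive", 1.0),
        TDLNBranch("b", "peritumoral", "positive", 1.0),
    ])
    traj = tk.simulate(net, dose, week_grid)
    np.testing.assert_allclose(traj.conc["PT/a"], traj.conc["PT/b"],
                               rtol=1e-9, atol=1e-12)


def test_tumor_status_partitions_total_vs_free_exposure(renal, dose, week_grid):
    # node target binds antibody: more total retained, less left free
    net = tk.apply_inflammation(renal, [
        TDLNBranch("pos", "peritumoral", "positive", 1.0),
        TDLNBranch("neg", "peritumoral", "negative", 1.0),
    ])
    states = integrate_network(net, net.initial_state(
        dose.plasma_concentration_nM(net.V_p)), week_grid)
    labels = net.state_labels()
    kd = renal.target.Kd

    def free_series(branch):
        ctot = states[:, labels.index(f"Ctot[PT/{branch}]")]
        rtot = states[:, labels.index(f"Rtot[PT/{branch}]")]
        return np.array([quasi_equilibrium_bind(c, r, kd).Cf
                         for c, r in zip(ctot, rtot)])

    tot_pos = np.trapezoid(states[:, labels.index("Ctot[PT/pos]")], week_grid)
    tot_neg = np.trapezoid(states[:, labels.index("Ctot[PT/neg]")], week_grid)
    free_pos = np.trapezoid(free_series("pos"), week_grid)
    free_neg = np.trapezoid(free_series("neg"), week_grid)
    assert tot_pos > tot_neg
    assert free_pos < free_neg


def test_multibranch_network_conserves_mass_without_sinks(renal, week_grid):
    s = renal.replace(CL_p=1e-300, k_int=0.0, R01=0.0, R02=0.0,
                      uptake_prob=0.0)
    net = tk.apply_inflammation(s, [
        TDLNBranch("intra", "intratumoral", "negative", 0.01),
        TDLNBranch("peri", "peritumoral", "negative", 2.0),
    ])
    y0 = net.initial_state(13.3)
    states = integrate_network(net, y0, week_grid)
    amount = states[:, 0] * net.V_p + states[:, 1] * net.V_isf_tissue
    col = 2
    for les in net.lesions:
        amount = amount + states[:, col] * les.V_isf
        col += 2
    for les in net.lesions:
        for node in les.tdlns:
            amount = amount + states[:, col] * node.V_isf
            col += 2
    assert np.max(np.abs(amount - amount[0])) / amount[0] < 1e-6


def test_inflammation_contract_errors(renal):
    with pytest.raises(ContractError):
        tk.apply_inflammation(renal, [TDLNBranch("only", "peritumoral")])
    with pytest.raises(ContractError):
        tk.apply_inflammation(renal, [
            TDLNBranch("a", "intratumoral", l_aff_multiplier=0.0),
            TDLNBranch("b", "intratumoral", l_aff_multiplier=0.0),
        ])
    with pytest.raises(InvalidParameterError):
        TDLNBranch("x", "sideways")


# ------------------------------------------------------------- JSON specs
def test_load_scenario_dispatch(renal, tmp_path):
    surg = tk.load_scenario({"type": "surgery", "lymph_reduction": 0.8}, renal)
    assert surg.physiology.L_aff == pytest.approx(0.0008)

    spec = {"type": "inflammation", "branches": [
        {"label": "intra", "position": "intratumoral", "tumor_status": "positive"},
        {"label": "peri", "position": "peritumoral"},
    ]}
    path = tmp_path / "inflammation.json"
    path.write_text(json.dumps(spec))
    net = tk.load_scenario(str(path), renal)
    assert [n.label for n in net.lesions[0].tdlns] == ["intra", "peri"]

    met = tk.load_scenario({"type": "metastasis", "metastases": [
        {"label": "lung_met", "organ_study": "bevacizumab_nsclc", "r01": 5.0},
    ]}, renal)
    assert [l.label for l in met.lesions] == ["PT", "lung_met"]
    assert met.lesions[1].target.R01 == 5.0

    with pytest.raises(ContractError):
        tk.load_scenario({"type": "mystery"}, renal)
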