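"""Least-squares calibration: recovery, diagnostics, contracts, I/O."""

import numpy as np
import pytest

import tdlnpk as tk
from tdlnpk import ContractError, FitSpec, InvalidParameterError, SUVObservation


@pytest.fixture(scope="module")
def noise_free_obs(renal, dose):
    obs, _ = tk.generate_observations(renal, dose, tk.ObservationDesign(cv=0.0))
    return obs


def test_noise_free_recovery_of_leakiness_and_clearance(renal, dose, noise_free_obs):
    spec = FitSpec(free=("sigma_v", "clp"),
                   initials={"sigma_v": 0.8, "clp": 0.08}, n_starts=1)
    res = tk.fit(noise_free_obs, spec, renal, dose)
    assert res.converged
    assert res.estimates["sigma_v"] == pytest.approx(0.97, rel=0.01)
    assert res.estimates["clp"] == pytest.approx(0.042, rel=0.01)
    assert res.objective < 1e-8


def test_objective_equals_recomputed_weighted_sse(renal, dose):
    obs, _ = tk.generate_observations(
        renal, dose, tk.ObservationDesign(cv=0.2, seed=11))
    spec = FitSpec(free=("clp",), n_starts=1)
    res = tk.fit(obs, spec, renal, dose)
    recomputed = float(np.sum((res.residuals["weight"]
                               * res.residuals["residual"]) ** 2))
    assert res.objective == pytest.approx(recomputed, rel=1e-9)


def test_observation_matching_initial_prediction_gives_zero_objective(renal, dose):
    traj = tk.simulate(renal, dose, np.array([0.0, 96.0]))
    obs = [SUVObservation("bevacizumab_renal", "PT", 96.0,
                          float(traj.suv["PT"][1]))]
    res = tk.fit(obs, FitSpec(free=("sigma_v",), n_starts=1), renal, dose)
    assert res.objective < 1e-12
    assert res.estimates["sigma_v"] == pytest.approx(0.97, abs=1e-4)


def test_plasma_only_data_cannot_identify_node_parameters(renal, dose, noise_free_obs):
    plasma_obs = [o for o in noise_free_obs if o.tissue == "plasma"]
    res = tk.fit(plasma_obs, FitSpec(free=("r01", "r02", "dln"), n_starts=1),
                 renal, dose)
    assert not res.identifiable
    assert len(res.uninformative) >= 1


def test_estimate_pinned_at_bound_is_flagged(renal, dose, noise_free_obs):
    # box excludes the true clearance 0.042: optimum lands on the lower edge
    spec = FitSpec(free=("clp",), bounds={"clp": (0.06, 0.2)}, n_starts=1)
    res = tk.fit(noise_free_obs, spec, renal, dose)
    assert res.at_bounds["clp"]
    assert res.estimates["clp"] == pytest.approx(0.06, abs=1e-6)


def test_widening_bounds_never_increases_objective(renal, dose, noise_free_obs):
    narrow = tk.fit(noise_free_obs,
                    FitSpec(free=("clp",), bounds={"clp": (0.06, 0.2)},
                            n_starts=1), renal, dose)
    wide = tk.fit(noise_free_obs,
                  FitSpec(free=("clp",), bounds={"clp": (0.001, 0.2)},
                          n_starts=1), renal, dose)
    assert wide.objective <= narrow.objective + 1e-12


def test_fit_contract_errors(renal, dose):
    with pytest.raises(ContractError):
        FitSpec(free=())
    with pytest.raises(InvalidParameterError):
        FitSpec(free=("warp_factor",))
    with pytest.raises(ContractError):
        tk.fit([], FitSpec(free=("clp",)), renal, dose)
    met_obs = [SUVObservation("x", "metastasis", 24.0, 1.0)]
    with pytest.raises(ContractError):
        tk.fit(met_obs, FitSpec(free=("clp",)), renal, dose)


def test_observation_validation():
    with pytest.raises(InvalidParameterError):
        SUVObservation("x", "muscle", 24.0, 1.0)
    with pytest.raises(InvalidParameterError):
        SUVObservation("x", "PT", -1.0, 1.0)
    with pytest.raises(InvalidParameterError):
        SUVObservation("x", "PT", 1.0, -0.5)


def test_csv_round_trip(tmp_path, noise_free_obs):
    path = tmp_path / "obs.csv"
    tk.write_observations_csv(noise_free_obs, path)
    back = tk.read_observations_csv(path)
    assert len(back) == len(noise_free_obs)
    for a, b in zip(back, noise_free_obs):
        assert a.tissue == b.tissue and a.time_h == b.time_h
        assert a.suv == pytest.approx(b.suv, rel=1e-12)
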