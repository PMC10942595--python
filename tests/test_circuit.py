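"""Circuit ODE model: steady states, quasi-equilibrium consistency,
population totals, and the calibrate/predict workflow."""

from dataclasses import replace

import numpy as np
import pytest

from transrep import synth
from transrep.circuit import (
    GrowthModel,
    calibrate,
    default_circuit,
    default_growth,
    headline_fold,
    predict_and_score,
    simulate_percell,
    simulate_population,
    steady_state,
)
from transrep.foldchange import FoldChangeContext, RegulationKinetics, fold_change
from transrep.presets import REDESIGN3_MAX_FOLD


class TestSteadyStates:
    def test_unregulated_reporter_level(self, circuit_model):
        ss = steady_state(circuit_model, 0.0)
        expected = (circuit_model.alpha_rep * circuit_model.beta_rep
                    / (circuit_model.delta_m * circuit_model.mu))
        assert ss["green"] == pytest.approx(expected, rel=1e-12)
        assert ss["rho"] == 1.0  # zero promoter leakiness, zero inducer

    def test_integration_converges_to_analytic_steady_state(self, circuit_model):
        t = np.linspace(0.0, 60.0, 40)  # 60 h is many protein lifetimes
        traj = simulate_percell(circuit_model, 1000.0, 0.0, t)
        ss = steady_state(circuit_model, 1000.0)
        for name in ("m_msi", "p_msi", "m_rep", "green", "red"):
            assert traj[name].iloc[-1] == pytest.approx(ss[name], rel=1e-6)

    def test_headline_repression_fold(self, circuit_model):
        assert headline_fold(circuit_model) == pytest.approx(2.5, rel=0.02)

    def test_redesign_leakage_preset_fold(self):
        model = default_circuit(leakage=1.0 / REDESIGN3_MAX_FOLD)
        assert headline_fold(model) == pytest.approx(8.6, rel=0.02)

    def test_oleic_acid_at_ic50_gives_intermediate_repression(self, circuit_model):
        full = steady_state(circuit_model, 1000.0, oleic_mM=0.0)
        half = steady_state(circuit_model, 1000.0,
                            oleic_mM=circuit_model.inh.ic50)
        none = steady_state(circuit_model, 0.0)
        assert full["green"] < half["green"] < none["green"]
        # at IC50 exactly half the repressor is active
        assert half["rho"] == pytest.approx(
            circuit_model.repression_factor(full["p_msi"] / 2), rel=1e-9
        )

    def test_quasi_equilibrium_matches_fold_change_model(self, rng):
        # the ODE repression factor is the stable-template (delta=0) fold change
        # with K_D = K_R, evaluated at the repressor steady state
        for _ in range(50):
            model = default_circuit(
                leakage=rng.uniform(0.05, 0.9),
                K_R=10 ** rng.uniform(-1, 2),
                p_saturating_nM=10 ** rng.uniform(1, 4),
            )
            ss = steady_state(model, 1000.0)
            kin = RegulationKinetics(k_on=1.0, k_off=model.K_R)
            ctx = FoldChangeContext(ss["p_msi"], model.leakage, 0.0)
            assert 1.0 / ss["rho"] == pytest.approx(fold_change(kin, ctx), rel=1e-6)

    def test_delta_must_exceed_dilution(self):
        with pytest.raises(ValueError, match="delta_m"):
            default_circuit(delta_m=0.001)


class TestPopulation:
    def test_logistic_early_slope_is_mu_max(self):
        growth = GrowthModel(mu_max=0.8, n0=1.0, n_cap=1e6)
        t = np.linspace(0.0, 1.0, 50)
        n = growth.population(t)
        slope = np.polyfit(t, np.log(n), 1)[0]
        assert slope == pytest.approx(0.8, rel=0.01)

    def test_population_at_capacity_stays_constant(self):
        growth = GrowthModel(mu_max=0.8, n0=100.0, n_cap=100.0)
        assert np.allclose(growth.population([0.0, 5.0, 50.0]), 100.0)

    def test_totals_are_products_of_parts(self, circuit_model, growth_model):
        t = np.linspace(0.25, 8.0, 12)
        res = simulate_population(circuit_model, growth_model, 100.0, 0.0, t)
        assert np.array_equal(res.total_green,
                              res.population * res.species["green"].to_numpy())
        ratio = res.total_green[1:] / res.total_red[1:]
        percell = (res.species["green"] / res.species["red"]).to_numpy()[1:]
        assert np.allclose(ratio, percell)  # population factor cancels exactly

    def test_invalid_initial_population_rejected(self):
        with pytest.raises(ValueError):
            GrowthModel(mu_max=0.8, n0=0.0, n_cap=10.0)


class TestCalibrate:
    def test_noise_free_self_consistency(self, circuit_model, growth_model):
        obs = synth.gen_totals_timeseries(circuit_model, growth_model,
                                          doses=(0.0, 1000.0), noise_cv=0.0,
                                          replicates=1, seed=0)
        start = replace(circuit_model, alpha_rep=circuit_model.alpha_rep * 2)
        gstart = replace(growth_model, mu_max=growth_model.mu_max * 1.3)
        fit_m, fit_g, loss = calibrate(start, gstart, obs,
                                       ["alpha_rep", "mu_max"])
        assert fit_m.alpha_rep == pytest.approx(circuit_model.alpha_rep, rel=1e-3)
        assert fit_g.mu_max == pytest.approx(growth_model.mu_max, rel=1e-3)

    def test_noisy_recovery_within_ten_percent(self, circuit_model, growth_model):
        obs = synth.gen_totals_timeseries(circuit_model, growth_model,
                                          doses=(0.0, 1000.0), noise_cv=0.05,
                                          replicates=3, seed=1)
        start = replace(circuit_model, alpha_rep=circuit_model.alpha_rep * 3)
        gstart = replace(growth_model, mu_max=growth_model.mu_max * 1.5,
                         n_cap=growth_model.n_cap * 0.5)
        fit_m, fit_g, _ = calibrate(start, gstart, obs,
                                    ["alpha_rep", "mu_max", "n_cap"])
        assert fit_m.alpha_rep == pytest.approx(circuit_model.alpha_rep, rel=0.10)
        assert fit_g.mu_max == pytest.approx(growth_model.mu_max, rel=0.10)
        assert fit_g.n_cap == pytest.approx(growth_model.n_cap, rel=0.10)

    def test_confounded_pair_rejected(self, circuit_model, growth_model):
        obs = synth.gen_totals_timeseries(circuit_model, growth_model,
                                          doses=(0.0, 1000.0), noise_cv=0.0,
                                          replicates=1, seed=0)
        with pytest.raises(ValueError, match="confounded"):
            calibrate(circuit_model, growth_model, obs,
                      ["alpha_rep", "beta_rep"])

    def test_missing_extreme_curve_rejected(self, circuit_model, growth_model):
        obs = synth.gen_totals_timeseries(circuit_model, growth_model,
                                          doses=(0.0,), noise_cv=0.0,
                                          replicates=1, seed=0)
        with pytest.raises(ValueError, match="1000"):
            calibrate(circuit_model, growth_model, obs, ["alpha_rep"])


class TestPredict:
    def test_noise_free_calibration_doses_score_perfectly(self, circuit_model,
                                                          growth_model):
        obs = synth.gen_totals_timeseries(circuit_model, growth_model,
                                          doses=(0.0, 1000.0), noise_cv=0.0,
                                          replicates=1, seed=0)
        score = predict_and_score(circuit_model, growth_model, [0.0, 1000.0],
                                  obs, include_calibration=True)
        assert score["r_squared"] >= 0.999

    def test_shuffled_observations_score_near_zero(self, circuit_model,
                                                   growth_model):
        obs = synth.gen_totals_timeseries(circuit_model, growth_model,
                                          noise_cv=0.0, replicates=1, seed=0)
        rng = np.random.default_rng(5)
        shuffled = obs.assign(
            total_green=rng.permutation(obs["total_green"].to_numpy())
        )
        score = predict_and_score(circuit_model, growth_model,
                                  sorted(obs["dose_uM"].unique()), shuffled)
        assert score["r_squared"] < 0.3

    def test_no_points_after_cutoff_rejected(self, circuit_model, growth_model):
        obs = synth.gen_totals_timeseries(circuit_model, growth_model,
                                          t_grid_h=np.linspace(0.25, 1.5, 5),
                                          noise_cv=0.0, replicates=1, seed=0)
        with pytest.raises(ValueError, match="beyond"):
            predict_and_score(circuit_model, growth_model,
                              sorted(obs["dose_uM"].unique()), obs, t_min_h=2.0)
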