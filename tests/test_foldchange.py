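"""Fold-change closed form: printed limits, mass-action oracle, regimes."""

import numpy as np
import pytest

from transrep import presets
from transrep.foldchange import (
    FoldChangeContext,
    RegulationKinetics,
    classify_regime,
    fold_change,
    fold_change_map,
    leakage_from_max_fold,
    mass_action_steady_state,
    max_fold,
)


class TestKinetics:
    def test_derived_fields_are_exact_ratios(self):
        kin = RegulationKinetics(k_on=1.1, k_off=1.0 / 1.5)
        assert kin.k_d == kin.k_off / kin.k_on
        assert kin.residence_time == 1.5

    @pytest.mark.parametrize("kwargs", [{"k_on": 0}, {"k_off": -1},
                                        {"k_on": float("nan")}])
    def test_invalid_rates_rejected(self, kwargs):
        full = {"k_on": 1.0, "k_off": 1.0, **kwargs}
        with pytest.raises(ValueError):
            RegulationKinetics(**full)


class TestFoldChange:
    def test_no_regulator_gives_unity(self, original_kinetics):
        ctx = FoldChangeContext(0.0, 0.1, 0.14)
        assert fold_change(original_kinetics, ctx) == 1.0

    def test_classical_equilibrium_limit(self, original_kinetics):
        # stable template, negligible leakage: fold = 1 + R/K_D, so R = K_D doubles
        ctx = FoldChangeContext(original_kinetics.k_d, 1e-12, 0.0)
        assert fold_change(original_kinetics, ctx) == pytest.approx(2.0, rel=1e-9)

    def test_two_state_worked_example(self):
        kin = RegulationKinetics(k_on=1.0, k_off=0.5)
        ctx = FoldChangeContext(1.0, 0.1, 0.14)
        assert fold_change(kin, ctx) == pytest.approx(1.64 / 0.74, rel=1e-12)

    def test_saturating_regulator_hits_leakage_ceiling(self, original_kinetics):
        eps = 0.1
        ctx = FoldChangeContext(1e9 * original_kinetics.k_d, eps, 0.14)
        assert fold_change(original_kinetics, ctx) == pytest.approx(1 / eps, rel=1e-3)

    def test_monotonic_in_each_parameter(self, rng):
        # fold rises with R and k_on, falls with k_off, delta, and leakage
        for _ in range(50):
            k_on, k_off = rng.uniform(0.01, 5, 2)
            r = rng.uniform(0.1, 100)
            eps = rng.uniform(0.05, 0.95)
            delta = rng.uniform(0.01, 1)
            base = fold_change(RegulationKinetics(k_on, k_off),
                               FoldChangeContext(r, eps, delta))
            assert fold_change(RegulationKinetics(k_on, k_off),
                               FoldChangeContext(r * 2, eps, delta)) >= base
            assert fold_change(RegulationKinetics(k_on * 2, k_off),
                               FoldChangeContext(r, eps, delta)) >= base
            assert fold_change(RegulationKinetics(k_on, k_off * 2),
                               FoldChangeContext(r, eps, delta)) <= base
            assert fold_change(RegulationKinetics(k_on, k_off),
                               FoldChangeContext(r, eps, delta * 2)) <= base
            assert fold_change(RegulationKinetics(k_on, k_off),
                               FoldChangeContext(r, min(eps * 2, 1), delta)) <= base


class TestMaxFold:
    @pytest.mark.parametrize("leakage,expected", [(0.4, 2.5), (1.0, 1.0),
                                                  (0.11628, pytest.approx(8.6, rel=1e-4))])
    def test_reciprocal_of_leakage(self, leakage, expected):
        assert max_fold(leakage) == expected

    @pytest.mark.parametrize("fold,expected", [(2.5, 0.40), (1.0, 1.0),
                                               (8.6, pytest.approx(0.1162790697))])
    def test_inversion(self, fold, expected):
        assert leakage_from_max_fold(fold) == expected

    def test_round_trip(self):
        for eps in (0.01, 0.4, 0.999):
            assert leakage_from_max_fold(max_fold(eps)) == pytest.approx(eps, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            max_fold(0.0)
        with pytest.raises(ValueError):
            leakage_from_max_fold(0.9)


class TestMassActionOracle:
    def test_steady_state_without_regulator(self, original_kinetics):
        m, b, flux = mass_action_steady_state(
            original_kinetics, FoldChangeContext(0.0, 0.4, 0.14), 7.0
        )
        assert m == pytest.approx(7.0 / 0.14)
        assert b == 0.0

    def test_bound_fraction_matches_linear_algebra(self, original_kinetics):
        ctx = FoldChangeContext(3.0, 0.4, 0.14)
        m, b, _ = mass_action_steady_state(original_kinetics, ctx)
        kon_r = original_kinetics.k_on * ctx.regulator_conc
        expected = kon_r / (kon_r + original_kinetics.k_off + ctx.degradation)
        assert b / (m + b) == pytest.approx(expected, rel=1e-12)

    def test_total_template_is_alpha_over_delta(self, original_kinetics):
        ctx = FoldChangeContext(10.0, 0.2, 0.3)
        m, b, _ = mass_action_steady_state(original_kinetics, ctx, 2.5)
        assert m + b == pytest.approx(2.5 / 0.3, rel=1e-12)

    def test_no_steady_state_for_stable_template(self, original_kinetics):
        with pytest.raises(ValueError):
            mass_action_steady_state(original_kinetics,
                                     FoldChangeContext(1.0, 0.4, 0.0))

    def test_closed_form_equals_flux_ratio_on_random_draws(self, rng):
        # 200 log-uniform parameter draws: relative error <= 1e-8
        for _ in range(200):
            kin = RegulationKinetics(
                10 ** rng.uniform(-3, 1), 10 ** rng.uniform(-3, 1)
            )
            ctx = FoldChangeContext(
                10 ** rng.uniform(-2, 4),
                10 ** rng.uniform(-2, 0),
                10 ** rng.uniform(-2, 0),
            )
            _, _, flux = mass_action_steady_state(kin, ctx)
            _, _, flux0 = mass_action_steady_state(
                kin, FoldChangeContext(0.0, ctx.leakage, ctx.degradation)
            )
            fold = fold_change(kin, ctx)
            assert abs(fold - flux0 / flux) / fold <= 1e-8


class TestFoldChangeMap:
    def test_single_cell_reduces_to_fold_change(self):
        fc_map = fold_change_map([1.0], [0.5], 0.1, 0.14)
        kin = RegulationKinetics(1.0, 0.5)
        expected = fold_change(kin, FoldChangeContext(1.0, 0.1, 0.14))
        assert fc_map.fold_matrix[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_isofold_contours_linear_without_degradation(self):
        # with delta=0 the iso-fold line is k_off = k_on*R*(1 - eps*f)/(f - 1)
        eps, f = 0.1, 2.0
        kon_r = np.array([0.01, 0.05, 0.2, 1.0, 5.0])
        koff = kon_r * (1 - eps * f) / (f - 1)
        fc_map = fold_change_map(kon_r, np.sort(koff), eps, 0.0)
        for i in range(len(kon_r)):
            j = np.searchsorted(np.sort(koff), koff[i])
            assert fc_map.fold_matrix[i, j] == pytest.approx(f, rel=1e-12)

    def test_degradation_compromises_slow_association(self):
        # k_on*R below delta caps the achievable fold well under 1/eps
        fc_map = fold_change_map([0.05], [0.01], 0.1, 0.14)
        assert fc_map.fold_matrix[0, 0] < 1.5

    def test_every_entry_at_least_one(self):
        grid = np.logspace(-3, 1, 20)
        fc_map = fold_change_map(grid, grid, 0.3, 0.14)
        assert np.all(fc_map.fold_matrix >= 1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fold_change_map([], [1.0], 0.1, 0.0)


class TestRegimes:
    def test_printed_exemplars_separate(self):
        ctx = FoldChangeContext(1000.0, 0.4, 0.14)
        assert classify_regime(presets.KINETICS_PRESETS["ms2cp"], ctx) == "non_equilibrium"
        assert classify_regime(presets.KINETICS_PRESETS["original"], ctx) == "equilibrium"

    def test_slow_association_is_degradation_limited(self):
        kin = RegulationKinetics(k_on=0.001, k_off=1.0)
        ctx = FoldChangeContext(70.0, 0.4, 0.14)  # k_on*R = delta/2
        assert classify_regime(kin, ctx) == "degradation_limited"

    def test_stable_template_has_no_regime(self, original_kinetics):
        with pytest.raises(ValueError):
            classify_regime(original_kinetics, FoldChangeContext(1.0, 0.4, 0.0))
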