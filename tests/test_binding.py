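"""Binding-trace simulation, referencing, and shared-rate kinetics fitting."""

import numpy as np
import pytest

from transrep import presets, synth
from transrep.binding import (
    BindingTrace,
    fit_kinetics,
    k_obs,
    kd_from_rates,
    kobs_regression,
    reference_trace,
    residence_from_koff,
    simulate_trace,
)


class TestDerivedConstants:
    def test_unit_consistent_rates_give_unit_kd(self):
        assert kd_from_rates(0.7, 0.7) == 1.0

    def test_phage_protein_dissociation_constant(self):
        # k_on = 0.032 /nM/min, residence 12 min
        assert kd_from_rates(0.032, 1.0 / 12.0) == pytest.approx(2.604, abs=1e-3)

    def test_original_motif_dissociation_constant(self):
        assert kd_from_rates(1.1, 1.0 / 1.5) == pytest.approx(0.606, abs=1e-3)

    def test_residence_time(self):
        assert residence_from_koff(1.0 / 1.5) == 1.5

    def test_kobs_reduces_to_koff_at_zero_concentration(self):
        assert k_obs(1.1, 0.6667, 0.0) == 0.6667

    def test_kobs_worked_example(self):
        assert k_obs(1.1, 0.6667, 5.0) == pytest.approx(6.167, abs=1e-3)


class TestSimulateTrace:
    def test_phase_boundaries(self):
        assoc, dissoc = simulate_trace(1.1, 0.6667, 5.0, 100.0)
        assert assoc.signal[0] == 0.0
        assert dissoc.signal[0] == pytest.approx(assoc.signal[-1])
        theta_eq = 1.1 * 5.0 / (1.1 * 5.0 + 0.6667)
        assert theta_eq == pytest.approx(0.8919, abs=1e-4)
        assert assoc.signal[-1] == pytest.approx(100.0 * theta_eq, rel=1e-3)

    def test_protocol_defaults(self):
        assoc, dissoc = simulate_trace(1.1, 0.6667, 5.0, 100.0)
        assert assoc.time_s[-1] == 300.0  # 5 min association at 1 Hz
        assert dissoc.time_s[-1] == 900.0  # 15 min dissociation
        assert np.all(np.diff(assoc.time_s) == 1.0)

    def test_seeded_noise_is_bit_reproducible(self):
        a1, d1 = simulate_trace(1.1, 0.6667, 5.0, 100.0, noise_sd=2.0, seed=11)
        a2, d2 = simulate_trace(1.1, 0.6667, 5.0, 100.0, noise_sd=2.0, seed=11)
        assert np.array_equal(a1.signal, a2.signal)
        assert np.array_equal(d1.signal, d2.signal)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(1.1, 0.6667, 0.0, 100.0)


class TestReferencing:
    def _flat(self, value, phase="association"):
        t = np.arange(0.0, 10.0)
        return BindingTrace(t, np.full(10, value), phase, 1.0)

    def test_identical_traces_cancel(self):
        tr = self._flat(5.0)
        out = reference_trace(tr, tr, tr)
        assert np.all(out.signal == 0.0)

    def test_zero_references_are_identity(self):
        sample, zero = self._flat(5.0), self._flat(0.0)
        assert np.array_equal(reference_trace(sample, zero, zero).signal,
                              sample.signal)

    def test_constant_offsets_subtract_exactly(self):
        out = reference_trace(self._flat(10.0), self._flat(2.0), self._flat(3.0))
        assert np.all(out.signal == 10.0 - 3.0)

    def test_grid_mismatch_rejected(self):
        short = BindingTrace(np.arange(5.0), np.zeros(5), "association", 1.0)
        with pytest.raises(ValueError):
            reference_trace(self._flat(1.0), short, short)


class TestFitKinetics:
    def test_noise_free_recovery(self, original_kinetics):
        traces = synth.gen_binding_traces(
            original_kinetics, [1.0, 5.0, 25.0], noise_sd=0.0, seed=0
        )
        fit = fit_kinetics(traces)
        assert fit.k_on == pytest.approx(original_kinetics.k_on, rel=1e-3)
        assert fit.k_off == pytest.approx(original_kinetics.k_off, rel=1e-3)
        assert fit.k_d == pytest.approx(original_kinetics.k_d, rel=1e-3)
        assert fit.residence_time == pytest.approx(1.5, rel=1e-3)

    def test_mutant_preset_kd(self):
        kin = presets.KINETICS_PRESETS["mutant5"]
        traces = synth.gen_binding_traces(kin, [20.0, 87.0, 400.0],
                                          noise_sd=0.0, seed=0)
        assert fit_kinetics(traces).k_d == pytest.approx(87.0, rel=1e-3)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_noisy_recovery_within_five_percent(self, original_kinetics, seed):
        # noise sd = 2% of amplitude, concentrations spanning K_D/5 .. 5 K_D
        kd = original_kinetics.k_d
        traces = synth.gen_binding_traces(
            original_kinetics, [kd / 5, kd, 5 * kd],
            amplitude=100.0, noise_sd=2.0, seed=seed,
        )
        fit = fit_kinetics(traces)
        assert fit.k_on == pytest.approx(original_kinetics.k_on, rel=0.05)
        assert fit.k_off == pytest.approx(original_kinetics.k_off, rel=0.05)

    def test_joint_and_sequential_orders_agree(self, original_kinetics):
        traces = synth.gen_binding_traces(
            original_kinetics, [1.0, 5.0, 25.0], noise_sd=1.0, seed=9
        )
        joint = fit_kinetics(traces, mode="joint")
        seq = fit_kinetics(traces, mode="sequential")
        assert seq.k_on == pytest.approx(joint.k_on, rel=0.05)
        assert seq.k_off == pytest.approx(joint.k_off, rel=0.05)

    def test_kobs_regression_cross_check(self, original_kinetics):
        traces = synth.gen_binding_traces(
            original_kinetics, [1.0, 5.0, 25.0], noise_sd=0.0, seed=0
        )
        k_on, k_off = kobs_regression(traces)
        assert k_on == pytest.approx(original_kinetics.k_on, rel=1e-3)
        assert k_off == pytest.approx(original_kinetics.k_off, rel=1e-2)

    def test_noise_free_residuals_negligible(self, original_kinetics):
        traces = synth.gen_binding_traces(
            original_kinetics, [1.0, 5.0], noise_sd=0.0, seed=0
        )
        fit = fit_kinetics(traces)
        assert fit.r_squared["association"] > 1 - 1e-9
        assert fit.r_squared["dissociation"] > 1 - 1e-9

    def test_global_fit_tightens_rate_precision(self, original_kinetics):
        # sharing rates across concentrations shrinks the k_on standard error
        multi = synth.gen_binding_traces(
            original_kinetics, [0.12, 0.6, 3.0], amplitude=100.0,
            noise_sd=2.0, seed=21,
        )
        single = [t for t in multi if t.analyte_conc in (0.0, 0.6)]
        fit_multi = fit_kinetics(multi)
        with pytest.warns(UserWarning):
            fit_single = fit_kinetics(single)
        assert fit_multi.stderr["k_on"] < fit_single.stderr["k_on"]

    def test_dissociation_only_unidentifiable(self, original_kinetics):
        _, dissoc = simulate_trace(original_kinetics.k_on,
                                   original_kinetics.k_off, 5.0, 100.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_kinetics([dissoc])

    def test_single_trace_warns_weak_identifiability(self, original_kinetics):
        pair = simulate_trace(original_kinetics.k_on, original_kinetics.k_off,
                              5.0, 100.0)
        with pytest.warns(UserWarning, match="weakly identifiable"):
            fit_kinetics(list(pair))
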