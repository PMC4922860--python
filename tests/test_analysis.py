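"""QC, fitting, idealization, open probability and I-V extraction."""

import math

import numpy as np
import pytest

from cagate import analysis as an
from cagate import gating, synth
from cagate.analysis import QCThresholds
from cagate.gating import CurrentTrace


def _trace(samples, dt=2e-4, **meta):
    return CurrentTrace(dt, [np.asarray(samples, dtype=float)], metadata=meta)


class TestQC:
    def _wc(self, seal, leak):
        return _trace(np.zeros(10), seal_resistance_gohm=seal, leak_at_minus60_pa=leak)

    def test_whole_cell_thresholds(self):
        bad_seal = self._wc(0.9, 10.0)
        bad_leak = self._wc(5.0, 95.0)
        good = self._wc(10.0, 0.0)
        kept, rejected = an.qc_filter([bad_seal, bad_leak, good], mode="whole-cell")
        assert kept == [good]
        assert len(rejected) == 2 and "seal" in rejected[0][1] and "leak" in rejected[1][1]

    def test_on_cell_boundary(self):
        low = _trace(np.zeros(10), seal_resistance_gohm=7.9)
        high = _trace(np.zeros(10), seal_resistance_gohm=8.1)
        kept, rejected = an.qc_filter([low, high], mode="on-cell")
        assert kept == [high] and rejected[0][0] is low

    def test_missing_metadata(self):
        kept, rejected = an.qc_filter([_trace(np.zeros(10))], mode="whole-cell")
        assert not kept and rejected[0][1] == "missing-metadata"


class TestExponentialFit:
    def test_noiseless_recovery(self):
        t = np.arange(0, 0.3, 2e-4)
        y = 0.0 + (-12.1) * np.exp(-t / 0.043)
        fit = an.fit_exponential(t, y)
        assert fit.converged
        assert fit.A == pytest.approx(-12.1, rel=1e-6)
        assert fit.tau == pytest.approx(0.043, rel=1e-6)

    def test_constant_input_unconverged(self):
        fit = an.fit_exponential(np.arange(100) * 1e-3, np.full(100, 3.0))
        assert not fit.converged and fit.A == 0.0

    def test_noisy_recovery_over_seeds(self):
        """tau recovered within 5% on average at sigma = 0.5 pA, 5 kHz, 200 ms."""
        t = np.arange(0, 0.2, 2e-4)
        truth = 0.043
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = -12.1 * np.exp(-t / truth) + rng.normal(0, 0.5, t.size)
            fit = an.fit_exponential(t, y)
            assert fit.converged
            errs.append(fit.tau / truth - 1.0)
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 0.05
        assert np.median(np.abs(errs)) < 0.05

    def test_too_few_samples(self):
        assert not an.fit_exponential([0, 1], [1, 0]).converged


class TestHillFit:
    def test_noiseless_ic50_recovery(self):
        df = synth.generate_dose_response(31.0, 1.0)
        fit = an.fit_hill(df["concentration_um"], df["response"])
        assert fit.converged
        assert fit.half_max == pytest.approx(31.0, rel=1e-3)
        assert fit.hill_n == pytest.approx(1.0, rel=1e-3)

    def test_flat_response_unconverged(self):
        fit = an.fit_hill([1, 10, 100, 1000], [0.0, 0.0, 0.0, 0.0])
        assert not fit.converged

    def test_midpoint_definition(self):
        df = synth.generate_dose_response(9.0, 1.0, concentrations=(9.0,) * 4)
        assert np.allclose(df["response"], 50.0)

    def test_steep_hill_coefficient_recovered(self):
        df = synth.generate_dose_response(31.0, 2.0)
        fit = an.fit_hill(df["concentration_um"], df["response"])
        assert fit.hill_n == pytest.approx(2.0, rel=1e-3)


class TestIdealize:
    def test_flat_zero_trace(self):
        rec = an.idealize(_trace(np.zeros(1000)), -12.1)
        assert rec.n_max == 0 and np.all(rec.level_per_sample == 0)

    def test_staircase_recovery(self):
        steps = np.concatenate([
            np.zeros(50), np.full(50, -12.1), np.full(50, -24.2),
            np.full(50, -12.1), np.zeros(50),
        ])
        rec = an.idealize(_trace(steps), -12.1, noise_sd=0.0)
        expected = np.concatenate([
            np.zeros(50), np.full(50, 1), np.full(50, 2), np.full(50, 1), np.zeros(50),
        ])
        assert np.array_equal(rec.level_per_sample, expected)
        assert rec.n_max == 2
        assert sum(d for _, d in rec.dwell_table) == pytest.approx(rec.total_time)

    def test_simulator_agreement_at_high_snr(self):
        """Idealized levels match the generating state paths >= 99% of samples."""
        from dataclasses import replace

        proto = gating.VoltageProtocol(
            (gating.Segment("hold", -100.0, -100.0, 20.0),), sample_interval=2e-4
        )
        params = replace(synth.make_fixture("unitary-iv").params, n_channels=3)
        trace, paths = gating.simulate_single_channels(
            proto, params, 5, erev=0.0, noise_sd=1.21,  # SNR 10
        )
        truth = np.sum([p == 1 for p in paths[0]], axis=0)
        rec = an.idealize(trace, -12.1)
        agreement = np.mean(rec.level_per_sample == truth)
        assert agreement >= 0.99

    def test_low_snr_warning(self):
        rng = np.random.default_rng(0)
        rec = an.idealize(_trace(rng.normal(0, 1.0, 5000)), -1.5)
        assert rec.low_snr_warning


class TestOpenProbability:
    def test_all_closed(self):
        rec = an.idealize(_trace(np.zeros(100)), -12.1)
        assert an.open_probability(rec, 1) == 0.0

    def test_half_open_single_channel(self):
        data = np.concatenate([np.zeros(500), np.full(500, -12.1)])
        rec = an.idealize(_trace(data), -12.1, noise_sd=0.0)
        assert an.open_probability(rec, 1) == pytest.approx(0.5)

    def test_scales_inversely_with_channel_count(self):
        data = np.concatenate([np.zeros(500), np.full(500, -12.1)])
        rec = an.idealize(_trace(data), -12.1, noise_sd=0.0)
        assert an.open_probability(rec, 4) == pytest.approx(0.125)

    def test_np_o_convention_when_count_unknown(self):
        data = np.concatenate([np.full(100, -24.2), np.zeros(100)])
        rec = an.idealize(_trace(data), -12.1, noise_sd=0.0)
        assert an.open_probability(rec) == pytest.approx(0.5)  # n = n_max = 2

    def test_zero_duration_rejected(self):
        rec = an.IdealizedRecord(np.array([], dtype=int), -12.1, 2e-4)
        with pytest.raises(ValueError):
            an.open_probability(rec, 1)

    def test_seeded_recovery_po(self, po_record):
        fix, trace, sidecar, rec = po_record
        est = an.open_probability(rec, fix.params.n_channels)
        n_events = int(np.clip(np.diff(rec.level_per_sample), 0, None).sum())
        se = est * math.sqrt(2.0 / n_events)
        assert est == pytest.approx(sidecar["p_o"], abs=2 * se)


class TestEnsembleAverage:
    def test_identical_sweeps(self):
        s = np.arange(10.0)
        assert np.array_equal(an.ensemble_average([s, s, s]), s)

    def test_sign_flipped_pair_cancels(self):
        s = np.arange(10.0)
        assert np.allclose(an.ensemble_average([s, -s]), 0.0)

    def test_ragged_sweeps_rejected(self):
        with pytest.raises(ValueError):
            an.ensemble_average([np.zeros(5), np.zeros(6)])

    def test_stochastic_tails_recover_macroscopic_tau(self):
        """20-pulse ensemble averages decay with the macroscopic tau.

        A single 20-pulse ensemble carries ~10^2 closure events, so its
        fitted tau scatters ~20%; the mean fitted tau over a handful of
        independent patches must land within the 25% small-n envelope.
        """
        fix = synth.make_fixture("single-channel-tail")
        w0, w1 = fix.protocol.segment_window(2)
        taus = []
        for seed in range(7):
            trace, sidecar = synth.generate_trace(fix, seed=seed)
            mean = an.ensemble_average(trace.sweeps)
            times = trace.times()
            mask = (times > w0) & (times <= w1)
            fit = an.fit_exponential(times[mask], mean[mask])
            assert fit.converged
            taus.append(fit.tau)
        assert np.mean(taus) == pytest.approx(0.043, rel=0.25)


class TestIVExtract:
    @staticmethod
    def _family_trace(erev, symmetric_g=False):
        proto = synth.make_protocol("iv-steps", sample_interval=5e-4)
        overrides = {"n_channels": 100}
        if symmetric_g:
            overrides.update(g_in=121.0, g_out=121.0)
        params = gating.parameter_set("wt", **overrides)
        occ = gating.simulate_occupancy(proto, params, math.inf)
        return gating.occupancy_to_current(occ, proto, params, erev=erev), proto

    def test_linear_ohmic_through_zero(self):
        trace, proto = self._family_trace(0.0, symmetric_g=True)
        res = an.iv_extract(trace, proto, "steady")
        assert res.erev_defined and res.erev == pytest.approx(0.0, abs=0.5)

    def test_constructed_reversal_recovered(self):
        trace, proto = self._family_trace(8.0, symmetric_g=True)
        res = an.iv_extract(trace, proto, "steady")
        assert res.erev == pytest.approx(8.0, abs=0.5)

    def test_reversal_within_half_grid_step_with_rectifying_conductance(self):
        # the inward/outward conductance kink bends the interpolation by
        # less than half the 5 mV voltage grid
        trace, proto = self._family_trace(8.0)
        res = an.iv_extract(trace, proto, "steady")
        assert res.erev == pytest.approx(8.0, abs=2.5)

    def test_all_positive_currents_undefined(self):
        proto = synth.make_protocol("iv-steps", sample_interval=5e-4)
        sweeps = [np.full(proto.samples_per_sweep(), 5.0) for _ in proto.family]
        trace = CurrentTrace(proto.sample_interval, sweeps, proto)
        res = an.iv_extract(trace, proto, "steady")
        assert not res.erev_defined and math.isnan(res.erev)


class TestCurrentDensity:
    def test_basic_and_sign(self):
        assert an.current_density(0.0, 10.0) == 0.0
        assert an.current_density(100.0, 10.0) == 10.0
        assert an.current_density(-100.0, 10.0) == -10.0

    def test_missing_capacitance(self):
        with pytest.raises(ValueError):
            an.current_density(1.0, 0.0)


class TestInactivationRate:
    def test_no_suprathreshold_sweeps(self):
        fit = an.inactivation_rate([1.0] * 6, [0.0] * 6)
        assert not fit.converged

    def test_sampled_exponential_recovery(self):
        # amplitudes generated as exp(-t/2.1 s) on the 0.2 Hz step grid
        t = np.arange(1, 13) * 2.5
        amp = np.exp(-t / 2.1)
        fit = an.inactivation_rate(amp, t)
        assert fit.converged and fit.tau == pytest.approx(2.1, rel=0.01)

    def test_invariant_to_amplitude_rescaling(self):
        t = np.arange(1, 13) * 2.5
        amp = np.exp(-t / 2.1)
        tau1 = an.inactivation_rate(amp, t).tau
        tau2 = an.inactivation_rate(1000 * amp, t).tau
        assert tau1 == pytest.approx(tau2, rel=1e-9)

    def test_simulated_series_recovers_k2(self, step_series_sim):
        proto, tails, supra = step_series_sim
        fit = an.inactivation_rate(tails, supra)
        assert fit.converged
        assert fit.tau == pytest.approx(2.1, rel=0.02)
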