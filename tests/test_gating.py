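"""Four-state gating model: rates, generator matrix, ODE and stochastic sims."""

import math

import numpy as np
import pytest

from cagate import analysis, gating, synth
from cagate.gating import (
    GatingParameters,
    Segment,
    VoltageProtocol,
    block_condition,
    generator_matrix,
    occupancy_to_current,
    rate_constants,
    simulate_occupancy,
    simulate_single_channels,
    unitary_current,
)


class TestRates:
    def test_reference_potential(self, wt_params):
        k1, km1 = rate_constants(0.0, wt_params)
        assert (k1, km1) == (wt_params.k1_0, wt_params.k_minus1_0)

    def test_voltage_fold_factors(self, wt_params):
        k1_100, _ = rate_constants(100.0, wt_params)
        _, km1_m100 = rate_constants(-100.0, wt_params)
        assert k1_100 == pytest.approx(1.5 * wt_params.k1_0)
        assert km1_m100 == pytest.approx(2.2 * wt_params.k_minus1_0)

    def test_wt_calibration_at_minus_100(self, wt_params):
        k1, km1 = rate_constants(-100.0, wt_params)
        assert k1 / (k1 + km1) == pytest.approx(0.007)
        assert 1.0 / (k1 + km1) == pytest.approx(0.043)

    def test_mutant_calibrations(self):
        for preset, tau in [("d523n", 0.0023), ("d525n", 0.037)]:
            p = gating.parameter_set(preset)
            k1, km1 = rate_constants(-100.0, p)
            assert 1.0 / (k1 + km1) == pytest.approx(tau)
        assert gating.parameter_set("d523n").k_block == 0.0

    def test_potentiation_multiplier_bounds(self):
        pot = gating.Potentiation()
        assert pot.multiplier(0.0) == 1.0
        assert pot.multiplier(300.0) == pytest.approx(2.0)
        assert pot.multiplier(1e9) == pytest.approx(3.0, rel=1e-3)


class TestBlockCondition:
    def test_no_driving_force_at_e_ca(self):
        assert not block_condition(100.0, 100.0)

    def test_outward_driving_force(self):
        assert block_condition(130.0, 100.0)

    def test_high_internal_ca_lowers_e_ca(self):
        # raising internal free Ca2+ drops E_Ca so +80 mV becomes blocking
        e_ca_rest = synth.uncaging_eca_source(1.0, 100.0, 20000.0)(0.5)
        e_ca_uncaged = synth.uncaging_eca_source(1.0, 100.0, 20000.0)(1.5)
        assert not block_condition(80.0, e_ca_rest)
        assert block_condition(80.0, e_ca_uncaged)


class TestGeneratorMatrix:
    def test_all_rates_zero_gives_zero_matrix(self):
        p = GatingParameters(k1_0=0, k_minus1_0=0, k_block=0, k_unblock=0,
                             k2=0, k_recover=0)
        assert np.all(generator_matrix(0.0, math.inf, p) == 0)

    def test_rows_sum_to_zero_and_offdiag_nonneg(self, wt_params):
        for v, e_ca in [(-100, math.inf), (150, 100.0), (50, 100.0)]:
            q = generator_matrix(v, e_ca, wt_params)
            assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
            off = q[~np.eye(4, dtype=bool)]
            assert np.all(off >= 0)

    def test_below_e_ca_only_two_states_active(self):
        p = GatingParameters(k1_0=10.0, k_minus1_0=25.0)
        q = generator_matrix(0.0, math.inf, p)
        assert q[0, 1] == 10.0 and q[1, 0] == 25.0
        assert q[0, 2] == q[1, 2] == q[2, 3] == 0.0
        # two-state equilibrium
        assert 10.0 / 35.0 == pytest.approx(0.2857, abs=1e-4)

    def test_open_state_mode_blocks_only_from_o(self, wt_params):
        from dataclasses import replace

        p = replace(wt_params, block_mode="open-state")
        q = generator_matrix(150.0, 100.0, p)
        assert q[1, 2] == p.k_block and q[0, 2] == 0.0
        q_coll = generator_matrix(150.0, 100.0, wt_params)
        assert q_coll[0, 2] == wt_params.k_block


def _hold_protocol(v, duration, dt=1e-3):
    return VoltageProtocol((Segment("hold", v, v, duration),), sample_interval=dt)


class TestSimulateOccupancy:
    def test_two_state_equilibrium_reached(self, wt_params):
        occ = simulate_occupancy(_hold_protocol(-60.0, 2.0), wt_params, math.inf)
        k1, km1 = rate_constants(-60.0, wt_params)
        assert occ.p_o[-1] == pytest.approx(k1 / (k1 + km1), rel=1e-6)
        assert np.all(np.abs(occ.p.sum(axis=1) - 1.0) < 1e-9)

    def test_instantaneous_matches_matrix_exponential(self, wt_params):
        from dataclasses import replace

        proto = _hold_protocol(-60.0, 0.5)
        occ_rate = simulate_occupancy(proto, wt_params, math.inf)
        occ_inst = simulate_occupancy(
            proto, replace(wt_params, block_speed="instantaneous"), math.inf
        )
        assert np.allclose(occ_rate.p, occ_inst.p, atol=1e-6)

    def test_suprathreshold_inactivation_follows_k2_law(self, wt_params):
        from dataclasses import replace

        p = replace(wt_params, block_speed="instantaneous")
        proto = _hold_protocol(150.0, 4.2, dt=1e-3)  # two time constants above E_Ca
        occ = simulate_occupancy(proto, p, 100.0)
        t_supra = occ.time[1:]
        expected = 1.0 - np.exp(-t_supra / 2.1)
        assert np.allclose(occ.p_i[1:], expected, atol=1e-3)

    def test_k2_zero_never_inactivates(self, wt_params):
        from dataclasses import replace

        p = replace(wt_params, k2=0.0, block_speed="instantaneous")
        occ = simulate_occupancy(_hold_protocol(150.0, 2.0), p, 100.0)
        assert np.all(occ.p_i == 0.0)

    def test_p_i_nondecreasing_without_recovery(self, wt_params):
        proto = synth.make_protocol(
            "step-series-0.2hz", n_below=1, n_above=3, sample_interval=1e-3
        )
        occ = simulate_occupancy(proto, wt_params, proto.metadata["e_ca_mv"])
        assert np.all(np.diff(occ.p_i) >= -1e-12)


class TestCurrents:
    def test_unitary_levels(self, wt_params):
        assert unitary_current(-100.0, 0.0, wt_params) == pytest.approx(-12.1)
        assert unitary_current(100.0, 0.0, wt_params) == pytest.approx(19.8)

    def test_zero_occupancy_zero_trace(self, wt_params):
        proto = _hold_protocol(-100.0, 0.1)
        occ = simulate_occupancy(proto, GatingParameters(k1_0=0.0, k_minus1_0=0.0), math.inf)
        trace = occupancy_to_current(occ, proto, wt_params, 0.0)
        assert np.all(trace.sweeps[0] == 0.0)

    def test_full_open_gives_ohmic_current(self, wt_params):
        proto = _hold_protocol(-100.0, 0.01)
        occ = simulate_occupancy(
            proto, GatingParameters(k1_0=1e6, k_minus1_0=0.0), math.inf,
            p0=[0.0, 1.0, 0.0, 0.0],
        )
        trace = occupancy_to_current(occ, proto, wt_params, 0.0)
        assert trace.sweeps[0][-1] == pytest.approx(-12.1, rel=1e-9)


class TestStochastic:
    def test_zero_channels_zero_current(self, wt_params):
        from dataclasses import replace

        proto = _hold_protocol(-100.0, 0.05)
        trace, paths = simulate_single_channels(
            proto, replace(wt_params, n_channels=0), 0
        )
        assert np.all(trace.sweeps[0] == 0.0) and paths[0] == []

    def test_seed_reproducibility(self, wt_params):
        from dataclasses import replace

        proto = _hold_protocol(-60.0, 0.5)
        p = replace(wt_params, n_channels=5)
        t1, s1 = simulate_single_channels(proto, p, 42, noise_sd=0.5)
        t2, s2 = simulate_single_channels(proto, p, 42, noise_sd=0.5)
        assert np.array_equal(t1.sweeps[0], t2.sweeps[0])
        assert all(np.array_equal(a, b) for a, b in zip(s1[0], s2[0]))

    def test_ensemble_matches_ode_within_three_se(self, wt_params):
        """Monte-Carlo open fraction tracks the ODE solution (3 SE envelope)."""
        from dataclasses import replace

        proto = synth.make_protocol("tail", tail_voltages=(-100.0,),
                                    sample_interval=1e-3)
        n = 3000
        p = replace(wt_params, n_channels=n)
        _, paths = simulate_single_channels(proto, p, 7)
        open_frac = np.mean([pp == 1 for pp in paths[0]], axis=0)
        occ = simulate_occupancy(proto, wt_params, math.inf)
        p_o = occ.p_o[1:]
        se = np.sqrt(np.maximum(p_o * (1 - p_o), 1e-9) / n)
        z = (open_frac - p_o) / se
        # pointwise 3 SE envelope, allowing rare excursions over 500 samples
        assert np.mean(np.abs(z) <= 3.0) > 0.99
        assert abs(z.mean()) < 1.0

    def test_long_record_recovers_constitutive_po(self, wt_params):
        """At -100 mV the generator's open fraction is the 0.007 equilibrium."""
        from dataclasses import replace

        proto = _hold_protocol(-100.0, 60.0, dt=1e-3)
        p = replace(wt_params, n_channels=20)
        _, paths = simulate_single_channels(
            proto, p, 11, p0=[0.993, 0.007, 0.0, 0.0]
        )
        arr = np.vstack(paths[0])
        est = (arr == 1).mean()
        n_open = int((np.diff((arr == 1).astype(int), axis=1) == 1).sum())
        se = 0.007 * math.sqrt(2.0 / max(n_open, 1))
        assert est == pytest.approx(0.007, abs=3 * se)


class TestIVShapes:
    """Steady-state outward I-V: biphasic for Wt, monotone for the no-block set."""

    @staticmethod
    def _steady_iv(params, e_ca):
        proto = synth.make_protocol("iv-steps", sample_interval=5e-4)
        occ = simulate_occupancy(proto, params, e_ca)
        trace = occupancy_to_current(occ, proto, params, erev=8.0)
        res = analysis.iv_extract(trace, proto, "steady")
        return res.v, res.i

    def test_wt_collapses_above_e_ca(self):
        params = gating.parameter_set("wt", n_channels=100,
                                      block_speed="instantaneous")
        v, i = self._steady_iv(params, e_ca=60.0)
        below = (v > 20) & (v < 55)
        above = v > 65
        # rising outward limb below E_Ca, collapsed above it
        assert np.all(np.diff(i[below]) > 0)
        assert i[above].max() < 0.05 * i[below].max()

    def test_no_block_set_stays_monotone(self):
        params = gating.parameter_set("d523n", n_channels=100,
                                      block_speed="instantaneous")
        v, i = self._steady_iv(params, e_ca=60.0)
        outward = v > 20
        assert np.all(np.diff(i[outward]) > 0)


class TestProtocolValidation:
    def test_segment_invariants(self):
        with pytest.raises(ValueError):
            Segment("hold", 0.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            Segment("ramp", 10.0, 10.0, 1.0)

    def test_sample_interval_must_divide_durations(self):
        with pytest.raises(ValueError, match="divide"):
            VoltageProtocol((Segment("hold", 0, 0, 0.0105),), sample_interval=1e-2)

    def test_family_length_checked(self):
        segs = (Segment("hold", 0, 0, 0.1), Segment("step", 10, 10, 0.1))
        with pytest.raises(ValueError):
            VoltageProtocol(segs, n_sweeps=3, family=(1.0, 2.0), family_segment=1)

    def test_total_duration_is_sum_of_segments(self):
        proto = synth.make_protocol("ramp-0.5hz", n_sweeps=1)
        assert proto.sweep_duration == pytest.approx(2.0)
        assert proto.sweep_voltages(0).size == proto.samples_per_sweep()
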