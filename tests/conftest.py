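"""Shared fixtures: expensive simulations are run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cagate import analysis, calcium, gating, synth


@pytest.fixture(scope="session")
def wt_params():
    return gating.wt_parameters()


@pytest.fixture(scope="session")
def step_series_sim():
    """Deterministic Fig-5-style 0.2 Hz depolarization series (Wt, 1 mM Ca2+).

    Returns (protocol, tail peak per sweep, cumulative suprathreshold time).
    """
    proto = synth.make_protocol("step-series-0.2hz")
    params = gating.parameter_set("wt", n_channels=100, block_speed="instantaneous")
    e_ca = proto.metadata["e_ca_mv"]
    occ = gating.simulate_occupancy(proto, params, e_ca)
    trace = gating.occupancy_to_current(occ, proto, params, erev=8.0)
    w0, w1 = proto.segment_window(2)
    times = trace.times()
    mask = (times >= w0) & (times <= w1)
    tails, supra, cum = [], [], 0.0
    for k in range(proto.n_sweeps):
        tails.append(trace.sweeps[k][mask].min())
        if proto.family[k] > e_ca:
            cum += proto.segments[1].duration
        supra.append(cum)
    return proto, np.asarray(tails), np.asarray(supra)


@pytest.fixture(scope="session")
def po_record():
    """Seeded multi-channel record generated at per-channel P_o = 0.0057."""
    fix = synth.make_fixture("single-channel-po")
    trace, sidecar = synth.generate_trace(fix, seed=1)
    rec = analysis.idealize(trace, sidecar["unitary_pa"])
    return fix, trace, sidecar, rec


@pytest.fixture(scope="session")
def coupled_runs():
    """Whole-cell feedback runs: 5 mM BAPTA (8 min) and 15+5 mM buffer (10 min)."""
    params = gating.parameter_set(
        "wt", n_channels=700, block_speed="instantaneous",
        potentiation=gating.Potentiation(),
    )
    low = calcium.coupled_whole_cell(
        synth.make_protocol("ramp-0.5hz", n_sweeps=240), params,
        buffers=(calcium.BufferSpec("BAPTA", 5.0, calcium.BAPTA_KD_UM),),
        initial_free_nm=100.0,
    )
    high = calcium.coupled_whole_cell(
        synth.make_protocol("ramp-0.5hz", n_sweeps=300), params,
        buffers=(calcium.BufferSpec("BAPTA", 15.0, calcium.BAPTA_KD_UM),
                 calcium.BufferSpec("EGTA", 5.0, calcium.EGTA_KD_UM)),
        initial_free_nm=15.0,
    )
    return low, high
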