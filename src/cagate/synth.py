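"""Synthetic recordings and fixtures: solutions, protocols, traces, dose-response.

Everything the analysis pipeline consumes can be generated here with a
fixed seed — macroscopic and single-channel current traces with Gaussian
baseline noise, the named recording solutions, the four stimulus protocols,
and Hill-law concentration-block tables.  Every generator records its own
ground-truth parameters in a sidecar mapping so recovery tests can close
the loop (fit the synthetic data, compare against the sidecar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calcium import BAPTA_KD_UM, EGTA_KD_UM, BufferSpec
from . import gating
from .gating import (
    CurrentTrace,
    GatingParameters,
    Segment,
    VoltageProtocol,
    parameter_set,
)
from .permeation import PAPER_GAMMA_TABLE, nernst_potential

__all__ = [
    "RecordingSolution",
    "NoiseModel",
    "FixtureSet",
    "POTENCIES_UM",
    "make_solutions",
    "make_protocol",
    "make_fixture",
    "generate_trace",
    "generate_dose_response",
    "uncaging_eca_source",
    "SOLUTION_PRESETS",
    "PROTOCOL_PRESETS",
    "FIXTURE_PRESETS",
]


@dataclass(frozen=True)
class RecordingSolution:
    """Ionic composition of one bath or pipette solution (mM)."""

    name: str
    ions: Mapping[str, float]  # component -> mM
    buffers: tuple[BufferSpec, ...] = ()
    free_ca_nm: float | None = None
    ph: float = 7.4
    divalent_free: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.ions.values()):
            raise ValueError("concentrations must be >= 0 mM")

    def cation_total(self, symbol: str) -> float:
        """Total concentration of a cation across its salts (mM).

        Understands the salt names used in the presets (e.g. Cs4-BAPTA
        contributes 4 Cs+ per formula unit).
        """
        total = 0.0
        for comp, mm in self.ions.items():
            if comp == f"{symbol}Cl" or comp == f"{symbol}Cl2" or comp == symbol:
                total += mm
            elif comp == f"{symbol}MES":
                total += mm
            elif comp == f"{symbol}4-BAPTA":
                total += 4.0 * mm
        return total


def _std_pipette() -> RecordingSolution:
    return RecordingSolution(
        "standard-pipette",
        {"CsMES": 80.0, "NaCl": 20.0, "HEPES": 10.0, "MgCl2": 2.0, "Cs4-BAPTA": 5.0},
        buffers=(BufferSpec("BAPTA", 5.0, BAPTA_KD_UM),),
        free_ca_nm=90.0,
    )


def _std_bath() -> RecordingSolution:
    return RecordingSolution("standard-bath", {"NaCl": 150.0, "HEPES": 10.0, "CaCl2": 2.0})


SOLUTION_PRESETS = {
    "standard": lambda: (_std_pipette(), _std_bath()),
    "dvf-symmetric-na": lambda: (
        RecordingSolution("dvf-pipette", {"NaCl": 144.0, "HEPES": 10.0},
                          divalent_free=True, free_ca_nm=1e-3),
        RecordingSolution("dvf-bath", {"NaCl": 144.0, "HEPES": 10.0},
                          divalent_free=True, free_ca_nm=1e-3),
    ),
    # on-cell single-channel configuration: standard saline in the pipette,
    # high-K+ bath to zero the resting membrane potential
    "high-k-bath": lambda: (
        _std_bath(),
        RecordingSolution("high-k-bath",
                          {"KCl": 125.0, "NaCl": 20.0, "HEPES": 10.0, "CaCl2": 2.0}),
    ),
    "nmdg-ca": lambda: (
        _std_pipette(),
        RecordingSolution("nmdg-ca-bath", {"NMDG": 100.0, "CaCl2": 20.0, "HEPES": 10.0}),
    ),
    "high-buffer": lambda: (
        RecordingSolution(
            "high-buffer-pipette",
            {"CsMES": 80.0, "NaCl": 20.0, "HEPES": 10.0,
             "BAPTA": 15.0, "EGTA": 5.0},
            buffers=(BufferSpec("BAPTA", 15.0, BAPTA_KD_UM),
                     BufferSpec("EGTA", 5.0, EGTA_KD_UM)),
            free_ca_nm=15.0,
        ),
        _std_bath(),
    ),
}


def make_solutions(preset: str) -> tuple[RecordingSolution, RecordingSolution]:
    """(pipette, bath) pair for a named preset."""
    if preset not in SOLUTION_PRESETS:
        raise KeyError(
            f"unknown solution preset {preset!r}; choose from {sorted(SOLUTION_PRESETS)}"
        )
    return SOLUTION_PRESETS[preset]()


# ---------------------------------------------------------------------------
# protocols


def _tail_protocol(tail_voltages: Sequence[float] = (-140, -120, -100, -80, -60, -40, -20),
                   sample_interval: float = 5e-5) -> VoltageProtocol:
    segs = (
        Segment("hold", 0.0, 0.0, 0.05),
        Segment("step", 100.0, 100.0, 0.15),
        Segment("step", -100.0, -100.0, 0.3),
    )
    return VoltageProtocol(
        segs, sample_interval=sample_interval, n_sweeps=len(tail_voltages),
        family=tuple(tail_voltages), family_segment=2, name="tail",
    )


def _ramp_protocol(n_sweeps: int = 240, sample_interval: float = 1e-3) -> VoltageProtocol:
    segs = (
        Segment("hold", -60.0, -60.0, 0.5),
        Segment("ramp", -100.0, 100.0, 1.0),
        Segment("hold", -60.0, -60.0, 0.5),
    )
    return VoltageProtocol(segs, sample_interval=sample_interval, n_sweeps=n_sweeps,
                           name="ramp-0.5hz")


def _step_series_protocol(
    e_ca: float = 103.7,
    n_below: int = 4,
    n_above: int = 12,
    below_offset: float = -20.0,
    above_offset: float = 35.0,
    sample_interval: float = 5e-4,
) -> VoltageProtocol:
    """0.2 Hz depolarization series bracketing E_Ca, tails at -60 mV.

    The default E_Ca corresponds to the 1 mM external / 90 nM internal free
    Ca2+ condition.  The first ``n_below`` sweeps step 20 mV below E_Ca
    (stable currents), the rest step ``above_offset`` mV above it, within
    the 28-42 mV range used experimentally.
    """
    family = tuple([e_ca + below_offset] * n_below + [e_ca + above_offset] * n_above)
    segs = (
        Segment("hold", -60.0, -60.0, 1.0),
        Segment("step", 0.0, 0.0, 2.5),
        Segment("hold", -60.0, -60.0, 1.5),
    )
    return VoltageProtocol(
        segs, sample_interval=sample_interval, n_sweeps=len(family),
        family=family, family_segment=1, name="step-series-0.2hz",
        metadata={"e_ca_mv": e_ca, "n_below": n_below,
                  "step_duration_s": 2.5},
    )


def _iv_steps_protocol(sample_interval: float = 2e-4) -> VoltageProtocol:
    family = tuple(float(v) for v in range(-100, 105, 5))
    segs = (
        Segment("hold", -60.0, -60.0, 0.05),
        Segment("step", 0.0, 0.0, 0.3),
        Segment("hold", -60.0, -60.0, 0.2),
    )
    return VoltageProtocol(segs, sample_interval=sample_interval, n_sweeps=len(family),
                           family=family, family_segment=1, name="iv-steps")


PROTOCOL_PRESETS = {
    "tail": _tail_protocol,
    "ramp-0.5hz": _ramp_protocol,
    "step-series-0.2hz": _step_series_protocol,
    "iv-steps": _iv_steps_protocol,
}


def make_protocol(preset: str, **kwargs) -> VoltageProtocol:
    """Build one of the named stimulus protocols."""
    if preset not in PROTOCOL_PRESETS:
        raise KeyError(
            f"unknown protocol preset {preset!r}; choose from {sorted(PROTOCOL_PRESETS)}"
        )
    return PROTOCOL_PRESETS[preset](**kwargs)


# ---------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class NoiseModel:
    """Additive recording noise: Gaussian baseline plus optional line hum."""

    gaussian_sd: float = 0.5  # pA
    line_frequency_amplitude: float = 0.0  # pA at 60 Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.line_frequency_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")

    def apply(self, trace: CurrentTrace, rng: np.random.Generator) -> CurrentTrace:
        if self.gaussian_sd == 0 and self.line_frequency_amplitude == 0:
            return trace
        t = trace.times()
        hum = self.line_frequency_amplitude * np.sin(2 * math.pi * 60.0 * t)
        sweeps = [
            s + hum + rng.normal(0.0, self.gaussian_sd, size=s.shape)
            for s in trace.sweeps
        ]
        return CurrentTrace(trace.sample_interval, sweeps, trace.protocol,
                            metadata=dict(trace.metadata))


@dataclass(frozen=True)
class FixtureSet:
    """A named, fully specified synthetic experiment.

    ``expected`` holds the generator's own ground-truth values so analysis
    operations can be validated against them.
    """

    name: str
    protocol: VoltageProtocol
    params: GatingParameters
    noise: NoiseModel = NoiseModel()
    erev: float = 0.0
    e_ca: float = math.inf
    stochastic: bool = False
    solutions: str = "standard"
    expected: Mapping[str, float] = field(default_factory=dict)


def _wt_tail_fixture() -> FixtureSet:
    params = parameter_set("wt", n_channels=500)
    return FixtureSet(
        "wt-tail", _tail_protocol(tail_voltages=(-100.0,)), params,
        noise=NoiseModel(gaussian_sd=0.0), erev=0.0, e_ca=math.inf,
        solutions="dvf-symmetric-na",
        expected={"tau_tail_s": 0.043, "p_o_minus100": 0.007},
    )


def _d523n_tail_fixture() -> FixtureSet:
    params = parameter_set("d523n", n_channels=500)
    return FixtureSet(
        "d523n-tail", _tail_protocol(tail_voltages=(-100.0,)), params,
        noise=NoiseModel(gaussian_sd=0.0), erev=0.0, e_ca=math.inf,
        solutions="dvf-symmetric-na",
        expected={"tau_tail_s": 0.0023},
    )


def _single_channel_po_fixture(record_s: float = 250.0, n_channels: int = 8) -> FixtureSet:
    """On-cell record at +80 mV with generator P_o exactly 0.0057 per channel.

    Multi-channel patches are the norm for this channel (up to 11
    simultaneous openings observed), so the default patch carries eight
    independent channels; with ~1100 openings the estimator's relative
    standard error is ~4%.  Mean open time 10 ms; the outward unitary
    current is 198 pS * 80 mV = 15.84 pA, well above the 0.5 pA noise.
    """
    p_o = 0.0057
    tau_o = 0.010  # s, mean open lifetime
    k_m1 = 1.0 / tau_o
    k1 = k_m1 * p_o / (1.0 - p_o)
    params = GatingParameters(
        k1_0=k1 / 1.5 ** 0.8, k_minus1_0=k_m1 / 2.2 ** -0.8,
        k_block=0.0, k2=0.0, n_channels=n_channels,
    )
    proto = VoltageProtocol(
        (Segment("hold", 80.0, 80.0, record_s),), sample_interval=2e-4, name="on-cell-hold",
    )
    return FixtureSet(
        "single-channel-po", proto, params, noise=NoiseModel(gaussian_sd=0.5),
        erev=0.0, e_ca=math.inf, stochastic=True, solutions="high-k-bath",
        expected={"p_o": p_o, "unitary_pa": 198.0 * 80.0 * 1e-3,
                  "mean_open_s": tau_o},
    )


def _unitary_iv_fixture(voltage: float = -100.0, record_s: float = 20.0) -> FixtureSet:
    """Mostly-open single channel at a negative potential (conductance fixture)."""
    params = GatingParameters(
        k1_0=45.0, k_minus1_0=5.0, fold_open_per_100mv=1.0,
        fold_close_per_100mv=1.0, k_block=0.0, k2=0.0, n_channels=1,
    )
    proto = VoltageProtocol(
        (Segment("hold", voltage, voltage, record_s),), sample_interval=2e-4,
        name="unitary-hold",
    )
    return FixtureSet(
        f"unitary-iv-{int(voltage)}", proto, params,
        noise=NoiseModel(gaussian_sd=0.5), erev=0.0, e_ca=math.inf, stochastic=True,
        solutions="dvf-symmetric-na",
        expected={"g_in_ps": 121.0, "unitary_pa": 121.0 * voltage * 1e-3,
                  "p_o": 0.9},
    )


def _single_channel_tail_fixture(n_sweeps: int = 20) -> FixtureSet:
    """Dense-patch tail sweeps for ensemble-average tests.

    Seeing up to 11 simultaneous openings at a tail-onset open probability
    of ~4% implies a patch of order 10^2 channels; 150 channels over 20
    pulses gives the ensemble mean enough events for a stable decay fit.
    """
    params = parameter_set("wt", n_channels=150)
    proto = replace(_tail_protocol(tail_voltages=(-100.0,)), n_sweeps=n_sweeps,
                    family=tuple([-100.0] * n_sweeps))
    return FixtureSet(
        "single-channel-tail", proto, params, noise=NoiseModel(gaussian_sd=0.5),
        erev=0.0, e_ca=math.inf, stochastic=True, solutions="dvf-symmetric-na",
        expected={"tau_tail_s": 0.043, "unitary_pa": -12.1},
    )


FIXTURE_PRESETS = {
    "wt-tail": _wt_tail_fixture,
    "d523n-tail": _d523n_tail_fixture,
    "single-channel-po": _single_channel_po_fixture,
    "unitary-iv": _unitary_iv_fixture,
    "single-channel-tail": _single_channel_tail_fixture,
}


def make_fixture(name: str, **kwargs) -> FixtureSet:
    if name not in FIXTURE_PRESETS:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_PRESETS)}")
    return FIXTURE_PRESETS[name](**kwargs)


def generate_trace(
    fixture: FixtureSet, seed: int | None = None
) -> tuple[CurrentTrace, dict]:
    """Simulate the fixture and return (trace, ground-truth sidecar).

    Deterministic given the seed (which defaults to the fixture's noise
    seed): the same seed yields byte-identical output.
    """
    rng = np.random.default_rng(fixture.noise.seed if seed is None else seed)
    if fixture.stochastic:
        trace, _paths = gating.simulate_single_channels(
            fixture.protocol, fixture.params, rng,
            e_ca_source=fixture.e_ca, erev=fixture.erev,
            noise_sd=0.0,
        )
        trace = fixture.noise.apply(trace, rng)
    else:
        occ = gating.simulate_occupancy(fixture.protocol, fixture.params, fixture.e_ca)
        trace = gating.occupancy_to_current(occ, fixture.protocol, fixture.params,
                                            fixture.erev)
        trace = fixture.noise.apply(trace, rng)
    sidecar = dict(fixture.expected)
    sidecar.update({
        "fixture": fixture.name,
        "seed": fixture.noise.seed if seed is None else seed,
        "noise_sd_pa": fixture.noise.gaussian_sd,
        "erev_mv": fixture.erev,
        "n_channels": fixture.params.n_channels,
        "g_in_ps": fixture.params.g_in,
        "g_out_ps": fixture.params.g_out,
    })
    trace.metadata.update(
        {"fixture": fixture.name, "seed": sidecar["seed"],
         "solutions": fixture.solutions}
    )
    return trace, sidecar


# ---------------------------------------------------------------------------
# dose-response


#: Half-maximal potencies (uM) from concentration-block/potentiation fits.
POTENCIES_UM: Mapping[str, Mapping[str, float]] = {
    "dibucaine": {"wt": 31.0, "d523n": 23.0},
    "cadmium": {"wt": 25.0, "d525n": 40.0},
    "zinc": {"wt": 156.0, "d525n": 209.0},
    "gadolinium": {"wt": 9.0, "d525n": 11.0},
    "lanthanum": {"wt": 3.0, "d525n": 1.0},
    "calmidazolium": {"wt": 2.6, "d523n": 9.0},  # EC50 (potentiation)
}


def generate_dose_response(
    half_max: float,
    hill_n: float = 1.0,
    concentrations: Sequence[float] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
    noise_sd: float = 0.0,
    *,
    floor: float = 0.0,
    ceiling: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill-law percent-block table with optional Gaussian noise (% points).

    Columns: concentration_um, response.  Noiseless generation at c =
    half_max gives exactly the midpoint response.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0 uM")
    if half_max <= 0:
        raise ValueError("half_max must be > 0 uM")
    response = floor + (ceiling - floor) / (1.0 + (half_max / c) ** hill_n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=response.shape)
    return pd.DataFrame({"concentration_um": c, "response": response})


def uncaging_eca_source(
    t_uncage: float,
    free_before_nm: float,
    free_after_nm: float,
    ca_ext_mm: float = 2.0,
):
    """E_Ca(t) for a flash-photolysis (caged Ca2+) experiment.

    Internal free Ca2+ steps instantaneously from ``free_before_nm`` to
    ``free_after_nm`` at ``t_uncage``; E_Ca follows by the Nernst relation
    with the tabulated external Ca2+ activity coefficient.
    """
    alpha_ext = PAPER_GAMMA_TABLE["Ca"] * ca_ext_mm * 1e-3

    def e_ca(t: float) -> float:
        free_nm = free_after_nm if t >= t_uncage else free_before_nm
        return nernst_potential(alpha_ext, free_nm * 1e-9, 2)

    return e_ca
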