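"""Four-state Markov gating model with outward-Ca2+ block and inactivation.

The scheme is

    C  <->  O  ->  O_block  ->  I
       k1/k-1   k_block      k2              (I -> C at k_recover, ~0)

Opening and closing rates are modestly voltage dependent (1.5x and 2.2x per
100 mV, in the directions that produce outward steady-state rectification
and faster tail decay on hyperpolarization).  Whenever the membrane
potential exceeds the Ca2+ equilibrium potential E_Ca, outwardly moving
Ca2+ occupies the selectivity filter: the open channel is blocked
(O -> O_block) and blocked channels inactivate at k2 (~1/2.1 s).  In the
default "collective" block mode the filter of every available channel is
occupied while the driving force is outward, so the non-inactivated pool
decays with exactly exp(-t_supra / (1/k2)) of cumulative suprathreshold
time; the classic open-state-only scheme is available with
``block_mode="open-state"``.

Units: mV, pA, pS, seconds.  State order everywhere is (C, O, O_block, I).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "STATE_NAMES",
    "Potentiation",
    "GatingParameters",
    "Segment",
    "VoltageProtocol",
    "StateOccupancy",
    "CurrentTrace",
    "wt_parameters",
    "d523n_parameters",
    "d525n_parameters",
    "parameter_set",
    "rate_constants",
    "block_condition",
    "generator_matrix",
    "simulate_occupancy",
    "occupancy_to_current",
    "unitary_current",
    "simulate_single_channels",
]

STATE_NAMES = ("C", "O", "O_block", "I")
_C, _O, _OB, _I = 0, 1, 2, 3

EcaSource = float | Callable[[float], float]


@dataclass(frozen=True)
class Potentiation:
    """Phenomenological Hill multiplier on the opening rate vs internal free Ca2+.

    multiplier = 1 + (g_max - 1) * c^h / (c^h + K^h), c in nM.
    Not constrained by single-channel data; used for qualitative
    potentiation-then-inactivation behaviour in coupled simulations.
    """

    g_max: float = 3.0
    k_pot_nm: float = 300.0
    hill: float = 2.0

    def multiplier(self, free_ca_nm: float) -> float:
        if free_ca_nm <= 0:
            return 1.0
        c_h = free_ca_nm**self.hill
        return 1.0 + (self.g_max - 1.0) * c_h / (c_h + self.k_pot_nm**self.hill)


@dataclass(frozen=True)
class GatingParameters:
    """Rate constants, voltage factors and conductances of the gating scheme."""

    k1_0: float = 0.24419  # opening rate at 0 mV, /s (Wt calibration)
    fold_open_per_100mv: float = 1.5
    k_minus1_0: float = 10.4971  # closing rate at 0 mV, /s
    fold_close_per_100mv: float = 2.2
    k_block: float = 5000.0  # /s, filter occupancy when driving force is outward
    k_unblock: float = 5000.0  # /s, filter clearing when driving force is inward
    k2: float = 1.0 / 2.1  # /s, O_block -> I
    k_recover: float = 0.0  # /s, I -> C (irreversible on experiment timescale)
    g_in: float = 121.0  # pS, inward unitary conductance
    g_out: float = 198.0  # pS, outward unitary conductance
    n_channels: int = 1
    potentiation: Potentiation | None = None
    block_mode: Literal["collective", "open-state"] = "collective"
    block_speed: Literal["rate", "instantaneous"] = "rate"

    def __post_init__(self) -> None:
        for name in ("k1_0", "k_minus1_0", "k_block", "k_unblock", "k2", "k_recover"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.g_in <= 0 or self.g_out <= 0:
            raise ValueError("conductances must be > 0 pS")
        if self.fold_open_per_100mv <= 0 or self.fold_close_per_100mv <= 0:
            raise ValueError("fold factors must be > 0")
        if self.n_channels < 0:
            raise ValueError("n_channels must be >= 0")


def _calibrated(tau_tail_s: float, p_open: float, at_mv: float = -100.0, **kwargs) -> GatingParameters:
    """Parameters whose two-state deactivation at ``at_mv`` has the given tau and P_o."""
    k_total = 1.0 / tau_tail_s
    k1_v = p_open * k_total
    k_m1_v = (1.0 - p_open) * k_total
    fold_open = kwargs.get("fold_open_per_100mv", 1.5)
    fold_close = kwargs.get("fold_close_per_100mv", 2.2)
    k1_0 = k1_v / fold_open ** (at_mv / 100.0)
    k_m1_0 = k_m1_v / fold_close ** (-at_mv / 100.0)
    return GatingParameters(k1_0=k1_0, k_minus1_0=k_m1_0, **kwargs)


def wt_parameters(**overrides) -> GatingParameters:
    """Wild-type set: tau_tail(-100 mV) = 43 ms, constitutive P_o(-100 mV) = 0.007."""
    return _calibrated(0.043, 0.007, **overrides)


def d523n_parameters(**overrides) -> GatingParameters:
    """Selectivity-filter mutant: tau_tail(-100 mV) = 2.3 ms, no outward-Ca2+ block."""
    overrides.setdefault("k_block", 0.0)
    overrides.setdefault("k2", 0.0)
    return _calibrated(0.0023, 0.007, **overrides)


def d525n_parameters(**overrides) -> GatingParameters:
    """Outer filter mutant: tau_tail(-100 mV) = 37 ms, blocks/inactivates like Wt."""
    return _calibrated(0.037, 0.007, **overrides)


def parameter_set(name: str, **overrides) -> GatingParameters:
    """Named parameter set: 'wt', 'd523n' or 'd525n'."""
    factories = {"wt": wt_parameters, "d523n": d523n_parameters, "d525n": d525n_parameters}
    try:
        return factories[name.lower()](**overrides)
    except KeyError:
        raise KeyError(f"unknown parameter set {name!r}; choose from {sorted(factories)}") from None


def rate_constants(
    v: float, params: GatingParameters, free_ca_nm: float | None = None
) -> tuple[float, float]:
    """Voltage-dependent opening/closing rates (k1, k_minus1) in /s.

    k1 grows ``fold_open_per_100mv``-fold per +100 mV depolarization;
    k_minus1 grows ``fold_close_per_100mv``-fold per 100 mV hyperpolarization.
    """
    k1 = params.k1_0 * params.fold_open_per_100mv ** (v / 100.0)
    k_m1 = params.k_minus1_0 * params.fold_close_per_100mv ** (-v / 100.0)
    if params.potentiation is not None and free_ca_nm is not None:
        k1 *= params.potentiation.multiplier(free_ca_nm)
    return k1, k_m1


def block_condition(v: float, e_ca: float) -> bool:
    """True iff the Ca2+ driving force is outward (v strictly above E_Ca)."""
    return v > e_ca


def generator_matrix(
    v: float,
    e_ca: float,
    params: GatingParameters,
    free_ca_nm: float | None = None,
) -> np.ndarray:
    """4x4 transition-rate matrix Q at potential ``v`` (rows sum to zero).

    Off-diagonal entry Q[i, j] is the rate from state i to state j.
    """
    k1, k_m1 = rate_constants(v, params, free_ca_nm)
    q = np.zeros((4, 4))
    q[_C, _O] = k1
    q[_O, _C] = k_m1
    if block_condition(v, e_ca):
        q[_O, _OB] = params.k_block
        if params.block_mode == "collective":
            q[_C, _OB] = params.k_block
        q[_OB, _I] = params.k2
    else:
        q[_OB, _O] = params.k_unblock
    q[_I, _C] = params.k_recover
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


# ---------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class Segment:
    """One stretch of the command waveform."""

    kind: Literal["hold", "step", "ramp"]
    v_start: float
    v_end: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0 s")
        if self.kind == "ramp" and self.v_start == self.v_end:
            raise ValueError("ramp must have v_start != v_end")
        if self.kind in ("hold", "step") and self.v_start != self.v_end:
            raise ValueError(f"{self.kind} segment must have v_start == v_end")


def _const(kind: str, v: float, duration: float) -> Segment:
    return Segment(kind, v, v, duration)  # type: ignore[arg-type]


@dataclass(frozen=True)
class VoltageProtocol:
    """Stimulus description: an ordered segment list repeated over sweeps.

    ``family`` optionally gives a per-sweep command voltage applied to the
    segment at index ``family_segment`` (step families, e.g. I-V series).
    ``sweep_interval`` is the sweep start-to-start period; any excess over
    the summed segment durations is spent at the first segment's voltage.
    """

    segments: tuple[Segment, ...]
    sample_interval: float = 2e-4
    n_sweeps: int = 1
    sweep_interval: float | None = None
    family: tuple[float, ...] | None = None
    family_segment: int | None = None
    name: str = ""
    metadata: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0 s")
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.family is not None:
            object.__setattr__(self, "family", tuple(self.family))
            if self.family_segment is None:
                raise ValueError("family requires family_segment")
            if len(self.family) != self.n_sweeps:
                raise ValueError("family length must equal n_sweeps")
        for seg in self.segments:
            n = seg.duration / self.sample_interval
            if abs(n - round(n)) > 1e-6:
                raise ValueError(
                    f"sample_interval does not divide segment duration {seg.duration}"
                )
        if self.sweep_interval is not None and self.sweep_interval < self.sweep_duration:
            raise ValueError("sweep_interval shorter than the segment list")

    @property
    def sweep_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def period(self) -> float:
        return self.sweep_interval if self.sweep_interval is not None else self.sweep_duration

    def sweep_segments(self, sweep: int) -> tuple[Segment, ...]:
        """Segment list of one sweep with the family voltage substituted."""
        segs = list(self.segments)
        if self.family is not None:
            v = self.family[sweep]
            old = segs[self.family_segment]
            if old.kind == "ramp":
                segs[self.family_segment] = Segment("ramp", old.v_start, v, old.duration)
            else:
                segs[self.family_segment] = Segment(old.kind, v, v, old.duration)
        gap = self.period - self.sweep_duration
        if gap > 1e-12:
            segs.append(_const("hold", segs[0].v_start, gap))
        return tuple(segs)

    def samples_per_sweep(self) -> int:
        return round(self.period / self.sample_interval)

    def sweep_times(self) -> np.ndarray:
        """Sample times within one sweep (left edges)."""
        n = self.samples_per_sweep()
        return np.arange(n) * self.sample_interval

    def sweep_voltages(self, sweep: int = 0) -> np.ndarray:
        """Command voltage at each sample of one sweep."""
        out = np.empty(self.samples_per_sweep())
        i = 0
        for seg in self.sweep_segments(sweep):
            n = round(seg.duration / self.sample_interval)
            if seg.kind == "ramp":
                # voltage at the midpoint of each sample interval
                frac = (np.arange(n) + 0.5) / n
                out[i : i + n] = seg.v_start + frac * (seg.v_end - seg.v_start)
            else:
                out[i : i + n] = seg.v_start
            i += n
        return out[: self.samples_per_sweep()]

    def segment_window(self, index: int) -> tuple[float, float]:
        """(t_start, t_end) of segment ``index`` within a sweep, seconds."""
        t0 = sum(s.duration for s in self.segments[:index])
        return t0, t0 + self.segments[index].duration


# ---------------------------------------------------------------------------
# containers


@dataclass
class StateOccupancy:
    """Time-resolved state probabilities (columns C, O, O_block, I)."""

    time: np.ndarray
    p: np.ndarray  # shape (n, 4)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[1] != 4:
            raise ValueError("occupancy must have four state columns")
        if self.p.shape[0] != self.time.shape[0]:
            raise ValueError("time and occupancy lengths differ")
        sums = self.p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9) or np.any(self.p < -1e-12):
            raise ValueError("occupancies must be probabilities summing to 1")

    @property
    def p_c(self) -> np.ndarray:
        return self.p[:, _C]

    @property
    def p_o(self) -> np.ndarray:
        return self.p[:, _O]

    @property
    def p_oblock(self) -> np.ndarray:
        return self.p[:, _OB]

    @property
    def p_i(self) -> np.ndarray:
        return self.p[:, _I]


@dataclass
class CurrentTrace:
    """Sampled membrane current, one array per sweep, in pA."""

    sample_interval: float
    sweeps: list[np.ndarray]
    protocol: VoltageProtocol | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = [np.asarray(s, dtype=float) for s in self.sweeps]
        if any(not np.all(np.isfinite(s)) for s in self.sweeps):
            raise ValueError("current samples must be finite")
        if len({s.shape for s in self.sweeps}) > 1:
            raise ValueError("sweeps must have equal length")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def times(self) -> np.ndarray:
        return np.arange(len(self.sweeps[0])) * self.sample_interval

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.sweeps)


# ---------------------------------------------------------------------------
# deterministic simulation


def _eca_at(e_ca_source: EcaSource, t: float) -> float:
    return e_ca_source(t) if callable(e_ca_source) else e_ca_source


def _free_ca_at(source, t: float) -> float | None:
    if source is None:
        return None
    return source(t) if callable(source) else source


def _two_state_update(p: np.ndarray, k1: float, k_m1: float, dt: float) -> None:
    """Exact C<->O relaxation over dt, leaving O_block and I untouched."""
    pool = p[_C] + p[_O]
    if pool <= 0:
        return
    rate = k1 + k_m1
    if rate == 0:
        return
    o_inf = pool * k1 / rate
    p[_O] = o_inf + (p[_O] - o_inf) * math.exp(-rate * dt)
    p[_C] = pool - p[_O]


def simulate_occupancy(
    protocol: VoltageProtocol,
    params: GatingParameters,
    e_ca_source: EcaSource = math.inf,
    *,
    p0: Sequence[float] | None = None,
    free_ca_source: float | Callable[[float], float] | None = None,
) -> StateOccupancy:
    """Solve dp/dt = p Q(V(t)) over all sweeps of ``protocol``.

    ``e_ca_source`` is the Ca2+ equilibrium potential, either fixed (mV; use
    +inf for no outward driving force anywhere) or a callable of global time.
    ``free_ca_source`` optionally supplies internal free Ca2+ in nM for the
    potentiation multiplier.  Piecewise-constant segments are propagated with
    the matrix exponential (or the exact closed form in instantaneous-block
    mode); occupancies are renormalised to unit sum to guard float drift.

    Returns the occupancy sampled at every protocol sample, concatenated
    across sweeps; the initial condition (default: all closed) is included
    as the first sample.
    """
    dt = protocol.sample_interval
    n_per = protocol.samples_per_sweep()
    p = np.zeros(4)
    if p0 is None:
        p[_C] = 1.0
    else:
        p[:] = p0
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("initial occupancy must sum to 1")

    total = n_per * protocol.n_sweeps
    out = np.empty((total + 1, 4))
    out[0] = p
    times = np.empty(total + 1)
    times[0] = 0.0

    instantaneous = params.block_speed == "instantaneous"
    cache: dict[tuple, np.ndarray] = {}
    idx = 1
    t = 0.0
    for sweep in range(protocol.n_sweeps):
        volts = protocol.sweep_voltages(sweep)
        for k in range(n_per):
            v = volts[k]
            e_ca = _eca_at(e_ca_source, t)
            ca_nm = _free_ca_at(free_ca_source, t)
            blocked = block_condition(v, e_ca)
            if instantaneous:
                k1, k_m1 = rate_constants(v, params, ca_nm)
                if blocked and params.k_block > 0:
                    if params.block_mode == "collective":
                        p[_OB] += p[_C] + p[_O]
                        p[_C] = p[_O] = 0.0
                    else:
                        p[_OB] += p[_O]
                        p[_O] = 0.0
                        # closed channels still open into the blocked filter
                        dc = p[_C] * -math.expm1(-k1 * dt)
                        p[_C] -= dc
                        p[_OB] += dc
                    if params.k2 > 0 and p[_OB] > 0:
                        d_i = p[_OB] * -math.expm1(-params.k2 * dt)
                        p[_OB] -= d_i
                        p[_I] += d_i
                else:
                    if p[_OB] > 0:
                        p[_O] += p[_OB]
                        p[_OB] = 0.0
                    _two_state_update(p, k1, k_m1, dt)
                if params.k_recover > 0 and p[_I] > 0:
                    d_c = p[_I] * -math.expm1(-params.k_recover * dt)
                    p[_I] -= d_c
                    p[_C] += d_c
            else:
                key = (round(v, 9), blocked, None if ca_nm is None else round(ca_nm, 6))
                prop = cache.get(key)
                if prop is None:
                    # only the sign of (v - e_ca) enters Q; use -inf/+inf sentinels
                    e_eff = -math.inf if blocked else math.inf
                    prop = expm(generator_matrix(v, e_eff, params, ca_nm) * dt)
                    cache[key] = prop
                p = p @ prop
            p = np.clip(p, 0.0, None)
            p /= p.sum()
            t += dt
            out[idx] = p
            times[idx] = t
            idx += 1
    return StateOccupancy(times, out)


def unitary_current(v: float, erev: float, params: GatingParameters) -> float:
    """Single open-channel current in pA; piecewise-ohmic with a kink at E_rev."""
    g = params.g_in if v < erev else params.g_out
    return g * (v - erev) * 1e-3


def occupancy_to_current(
    occ: StateOccupancy,
    protocol: VoltageProtocol,
    params: GatingParameters,
    erev: float = 0.0,
) -> CurrentTrace:
    """Macroscopic current I = N * p_O * g(V) * (V - E_rev); pA.

    Only the O state conducts; O_block and I are non-conducting.
    """
    n_per = protocol.samples_per_sweep()
    sweeps = []
    for sweep in range(protocol.n_sweeps):
        volts = protocol.sweep_voltages(sweep)
        # occupancy sample i+1 corresponds to the end of sample interval i
        p_open = occ.p_o[1 + sweep * n_per : 1 + (sweep + 1) * n_per]
        g = np.where(volts < erev, params.g_in, params.g_out)
        sweeps.append(params.n_channels * p_open * g * (volts - erev) * 1e-3)
    return CurrentTrace(protocol.sample_interval, sweeps, protocol,
                        metadata={"erev_mv": erev, "n_channels": params.n_channels})


# ---------------------------------------------------------------------------
# stochastic simulation


def _constant_q_intervals(protocol: VoltageProtocol, sweep: int) -> list[tuple[float, float, float]]:
    """(t_start, t_end, v) pieces of one sweep over which V is constant.

    Ramps are subdivided at the sample grid (V taken at interval midpoints),
    so the chain is piecewise time-homogeneous and can be simulated exactly.
    """
    dt = protocol.sample_interval
    pieces: list[tuple[float, float, float]] = []
    t = 0.0
    for seg in protocol.sweep_segments(sweep):
        n = round(seg.duration / dt)
        if seg.kind == "ramp":
            for j in range(n):
                frac = (j + 0.5) / n
                v = seg.v_start + frac * (seg.v_end - seg.v_start)
                pieces.append((t + j * dt, t + (j + 1) * dt, v))
        else:
            pieces.append((t, t + seg.duration, seg.v_start))
        t += seg.duration
    return pieces


def simulate_single_channels(
    protocol: VoltageProtocol,
    params: GatingParameters,
    seed: int | np.random.Generator,
    *,
    e_ca_source: EcaSource = math.inf,
    erev: float = 0.0,
    noise_sd: float = 0.0,
    p0: Sequence[float] | None = None,
) -> tuple[CurrentTrace, list[list[np.ndarray]]]:
    """Event-driven stochastic simulation of ``params.n_channels`` channels.

    Each channel is an independent continuous-time Markov chain simulated
    exactly over the piecewise-constant voltage intervals of the protocol
    (exponential waiting times, per-interval rate matrices).  Channel state
    carries over between sweeps.  Returns the summed ohmic current (plus
    optional Gaussian noise) and, per sweep, one state-index array per
    channel sampled on the protocol grid.

    Reproducible: a fixed integer ``seed`` yields identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff = params
    if params.block_speed == "instantaneous":
        eff = replace(
            params,
            k_block=1e5 if params.k_block > 0 else 0.0,
            k_unblock=1e5 if params.k_unblock > 0 else 0.0,
            block_speed="rate",
        )

    n_per = protocol.samples_per_sweep()
    dt = protocol.sample_interval
    n_ch = eff.n_channels

    if p0 is None:
        states = np.zeros(n_ch, dtype=np.int64)
    else:
        states = rng.choice(4, size=n_ch, p=np.asarray(p0, dtype=float))

    sweeps_current: list[np.ndarray] = []
    state_paths: list[list[np.ndarray]] = []
    t_sweep0 = 0.0
    for sweep in range(protocol.n_sweeps):
        volts = protocol.sweep_voltages(sweep)
        paths = np.empty((n_ch, n_per), dtype=np.int64)
        for (t0, t1, v) in _constant_q_intervals(protocol, sweep):
            e_ca = _eca_at(e_ca_source, t_sweep0 + 0.5 * (t0 + t1))
            q = generator_matrix(v, e_ca, eff)
            exit_rates = -np.diag(q)
            # per-state cumulative jump distributions (cheap inverse-CDF draws)
            jump_cdf: list[np.ndarray | None] = []
            for s in range(4):
                if exit_rates[s] > 0:
                    probs = q[s].clip(min=0.0)
                    probs[s] = 0.0
                    jump_cdf.append(np.cumsum(probs / probs.sum()))
                else:
                    jump_cdf.append(None)
            i0 = round(t0 / dt)
            i1 = round(t1 / dt)
            # samples k in [i0, i1) record the state at the end of interval k
            sample_ends = (np.arange(i0, i1) + 1) * dt
            for ch in range(n_ch):
                s = states[ch]
                t = t0
                jump_times: list[float] = []
                seq = [s]
                while True:
                    rate = exit_rates[s]
                    if rate <= 0:
                        break
                    t_jump = t + rng.exponential(1.0 / rate)
                    if t_jump >= t1:
                        break
                    s = int(np.searchsorted(jump_cdf[s], rng.random()))
                    t = t_jump
                    jump_times.append(t)
                    seq.append(s)
                if jump_times:
                    pos = np.searchsorted(np.asarray(jump_times), sample_ends, side="right")
                    paths[ch, i0:i1] = np.asarray(seq)[pos]
                else:
                    paths[ch, i0:i1] = s
                states[ch] = s
        g = np.where(volts < erev, eff.g_in, eff.g_out)
        open_counts = (paths == _O).sum(axis=0)
        current = open_counts * g * (volts - erev) * 1e-3
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, size=current.shape)
        sweeps_current.append(current)
        state_paths.append([paths[ch].copy() for ch in range(n_ch)])
        t_sweep0 += protocol.period
    trace = CurrentTrace(protocol.sample_interval, sweeps_current, protocol,
                         metadata={"erev_mv": erev, "n_channels": n_ch,
                                   "noise_sd_pa": noise_sd})
    return trace, state_paths
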