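"""Measurement operations for patch-clamp records.

Quality-control filtering, single-exponential and Hill fits, multi-level
half-amplitude idealization, open probability, ensemble averaging, I-V /
reversal-potential extraction and the cumulative-suprathreshold-time
inactivation fit.  Fits are nonlinear least squares (scipy) wrapped in a
:class:`FitResult` that carries estimates, residual RMS and a convergence
flag; degenerate inputs are flagged, never silently fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .gating import CurrentTrace, VoltageProtocol

__all__ = [
    "FitResult",
    "IdealizedRecord",
    "QCThresholds",
    "IVResult",
    "qc_filter",
    "fit_exponential",
    "fit_hill",
    "idealize",
    "open_probability",
    "ensemble_average",
    "iv_extract",
    "current_density",
    "inactivation_rate",
]


@dataclass
class FitResult:
    """Estimates and diagnostics of a model fit."""

    model: Literal["exponential", "hill"]
    params: dict[str, float]
    residual_rms: float
    converged: bool
    n_points: int
    message: str = ""

    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["params"][name]
        except KeyError:
            raise AttributeError(name) from None


@dataclass
class IdealizedRecord:
    """Multi-level idealization of a single-channel record.

    level_per_sample holds the number of simultaneously open channels at
    each sample; dwell_table lists (level, duration_s) runs.
    """

    level_per_sample: np.ndarray
    unitary_amplitude: float
    sample_interval: float
    low_snr_warning: bool = False

    def __post_init__(self) -> None:
        self.level_per_sample = np.asarray(self.level_per_sample, dtype=np.int64)
        if np.any(self.level_per_sample < 0):
            raise ValueError("levels must be >= 0")

    @property
    def n_max(self) -> int:
        return int(self.level_per_sample.max(initial=0))

    @property
    def total_time(self) -> float:
        return self.level_per_sample.size * self.sample_interval

    @property
    def dwell_table(self) -> list[tuple[int, float]]:
        levels = self.level_per_sample
        if levels.size == 0:
            return []
        edges = np.flatnonzero(np.diff(levels)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [levels.size]])
        return [(int(levels[s]), float((e - s) * self.sample_interval))
                for s, e in zip(starts, ends)]


@dataclass(frozen=True)
class QCThresholds:
    """Recording-quality cutoffs (strict inequalities, as applied in practice)."""

    min_seal_whole_cell: float = 1.0  # GOhm; below this: insufficient voltage control
    max_leak_at_minus60: float = 90.0  # pA
    min_seal_on_cell: float = 8.0  # GOhm

    def __post_init__(self) -> None:
        if min(self.min_seal_whole_cell, self.max_leak_at_minus60, self.min_seal_on_cell) <= 0:
            raise ValueError("thresholds must be positive")


def qc_filter(
    traces: Sequence[CurrentTrace],
    thresholds: QCThresholds = QCThresholds(),
    mode: Literal["whole-cell", "on-cell"] = "whole-cell",
) -> tuple[list[CurrentTrace], list[tuple[CurrentTrace, str]]]:
    """Partition traces into (kept, [(rejected, reason), ...]).

    Whole-cell records are rejected when seal resistance < 1 GOhm or leak at
    -60 mV > 90 pA; on-cell records when seal < 8 GOhm.  Traces lacking the
    relevant metadata are rejected with reason 'missing-metadata'.
    """
    kept: list[CurrentTrace] = []
    rejected: list[tuple[CurrentTrace, str]] = []
    for tr in traces:
        meta = tr.metadata
        seal = meta.get("seal_resistance_gohm")
        if mode == "whole-cell":
            leak = meta.get("leak_at_minus60_pa")
            if seal is None or leak is None:
                rejected.append((tr, "missing-metadata"))
            elif seal < thresholds.min_seal_whole_cell:
                rejected.append((tr, f"seal {seal:g} GOhm < {thresholds.min_seal_whole_cell:g}"))
            elif leak > thresholds.max_leak_at_minus60:
                rejected.append((tr, f"leak {leak:g} pA > {thresholds.max_leak_at_minus60:g}"))
            else:
                kept.append(tr)
        elif mode == "on-cell":
            if seal is None:
                rejected.append((tr, "missing-metadata"))
            elif seal < thresholds.min_seal_on_cell:
                rejected.append((tr, f"seal {seal:g} GOhm < {thresholds.min_seal_on_cell:g}"))
            else:
                kept.append(tr)
        else:
            raise ValueError(f"unknown QC mode {mode!r}")
    return kept, rejected


def _exp_model(t: np.ndarray, b: float, a: float, tau: float) -> np.ndarray:
    return b + a * np.exp(-t / tau)


def fit_exponential(time: Sequence[float], current: Sequence[float]) -> FitResult:
    """Least-squares fit of f(t) = B + A exp(-t/tau) (decaying form).

    Time is re-zeroed to the first sample.  Exact on noiseless exponentials;
    a constant input leaves tau unidentifiable and is flagged unconverged.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(current, dtype=float)
    if t.size < 10:
        return FitResult("exponential", {}, math.nan, False, t.size, "need >= 10 samples")
    t = t - t[0]
    spread = y.max() - y.min()
    if spread <= 1e-12 * max(1.0, abs(y).max()):
        return FitResult(
            "exponential", {"B": float(y.mean()), "A": 0.0, "tau": math.nan},
            0.0, False, t.size, "constant input: tau unidentifiable",
        )
    b0 = float(y[int(0.9 * y.size):].mean())
    a0 = float(y[0] - b0)
    # crude tau guess: time to decay to 1/e of the initial excess
    excess = np.abs(y - b0)
    idx = np.flatnonzero(excess <= abs(a0) / math.e)
    tau0 = float(t[idx[0]]) if idx.size and t[idx[0]] > 0 else float(t[-1] / 5.0)
    try:
        popt, _ = curve_fit(
            _exp_model, t, y, p0=(b0, a0, max(tau0, t[1])),
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return FitResult("exponential", {}, math.nan, False, t.size, f"fit failed: {exc}")
    resid = y - _exp_model(t, *popt)
    return FitResult(
        "exponential",
        {"B": float(popt[0]), "A": float(popt[1]), "tau": float(popt[2])},
        float(np.sqrt(np.mean(resid**2))), True, t.size,
    )


def _hill_model(c: np.ndarray, half: float, n: float, floor: float, ceiling: float) -> np.ndarray:
    return floor + (ceiling - floor) / (1.0 + (half / c) ** n)


def fit_hill(
    concentrations: Sequence[float],
    response: Sequence[float],
    *,
    hill_bounds: tuple[float, float] = (0.3, 4.0),
    fix_floor: float | None = None,
) -> FitResult:
    """Hill fit of a concentration-response table; reports half_max (IC50/EC50).

    response = floor + (ceiling - floor) / (1 + (half_max/c)^hill_n).
    The Hill coefficient is free within ``hill_bounds`` by default.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.size < 4:
        return FitResult("hill", {}, math.nan, False, c.size, "need >= 4 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    spread = y.max() - y.min()
    if spread <= 1e-9 * max(1.0, abs(y).max()):
        return FitResult("hill", {}, math.nan, False, c.size, "flat response")
    order = np.argsort(c)
    c, y = c[order], y[order]
    floor0 = float(y[0]) if fix_floor is None else fix_floor
    ceil0 = float(y[-1])
    mid = 0.5 * (floor0 + ceil0)
    above = np.flatnonzero((y - mid) * (ceil0 - floor0) >= 0)
    half0 = float(np.sqrt(c[above[0]] * c[max(above[0] - 1, 0)])) if above.size else float(np.median(c))

    if fix_floor is None:
        def model(cc, half, n, floor, ceiling):
            return _hill_model(cc, half, n, floor, ceiling)
        p0 = (half0, 1.0, floor0, ceil0)
        lb = [c.min() * 1e-4, hill_bounds[0], -np.inf, -np.inf]
        ub = [c.max() * 1e4, hill_bounds[1], np.inf, np.inf]
    else:
        def model(cc, half, n, ceiling):
            return _hill_model(cc, half, n, fix_floor, ceiling)
        p0 = (half0, 1.0, ceil0)
        lb = [c.min() * 1e-4, hill_bounds[0], -np.inf]
        ub = [c.max() * 1e4, hill_bounds[1], np.inf]
    try:
        popt, _ = curve_fit(model, c, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return FitResult("hill", {}, math.nan, False, c.size, f"fit failed: {exc}")
    fitted = model(c, *popt)
    resid = y - fitted
    params = {"half_max": float(popt[0]), "hill_n": float(popt[1])}
    if fix_floor is None:
        params["floor"], params["ceiling"] = float(popt[2]), float(popt[3])
    else:
        params["floor"], params["ceiling"] = fix_floor, float(popt[2])
    return FitResult("hill", params, float(np.sqrt(np.mean(resid**2))), True, c.size)


def idealize(
    trace: CurrentTrace | np.ndarray,
    unitary_amplitude: float,
    sample_interval: float | None = None,
    noise_sd: float | None = None,
) -> IdealizedRecord:
    """Half-amplitude multi-level idealization of a baseline-subtracted record.

    Each sample is assigned level = round(I / unitary_amplitude), clipped at
    zero (``unitary_amplitude`` is signed: negative for inward openings).
    If the amplitude is within 2 noise SDs the record is flagged low-SNR
    (noise SD estimated from first differences when not supplied).
    """
    if unitary_amplitude == 0:
        raise ValueError("unitary amplitude must be nonzero")
    if isinstance(trace, CurrentTrace):
        data = trace.concatenated()
        dt = trace.sample_interval
    else:
        data = np.asarray(trace, dtype=float)
        if sample_interval is None:
            raise ValueError("sample_interval required for a bare array")
        dt = sample_interval
    if noise_sd is None:
        noise_sd = float(np.median(np.abs(np.diff(data))) / (math.sqrt(2) * 0.6745))
    levels = np.clip(np.round(data / unitary_amplitude).astype(np.int64), 0, None)
    return IdealizedRecord(
        levels, unitary_amplitude, dt,
        low_snr_warning=abs(unitary_amplitude) <= 2.0 * noise_sd,
    )


def open_probability(rec: IdealizedRecord, n_channels: int | None = None) -> float:
    """Time-averaged open probability from an idealized record.

    P_o = sum_k level_k * dwell_k / (N * total_time).  When the channel
    count is unknown (or smaller than the highest observed level) the
    maximum simultaneous level is used as N — the NP_o convention.
    """
    if rec.total_time <= 0:
        raise ValueError("record has zero duration")
    n_eff = rec.n_max if n_channels is None or n_channels < rec.n_max else n_channels
    if n_eff == 0:
        return 0.0
    open_time = float(rec.level_per_sample.sum()) * rec.sample_interval
    return open_time / (n_eff * rec.total_time)


def ensemble_average(sweeps: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise mean of equal-length sweeps."""
    arrays = [np.asarray(s, dtype=float) for s in sweeps]
    if not arrays:
        raise ValueError("no sweeps to average")
    if len({a.shape for a in arrays}) > 1:
        raise ValueError("sweeps have unequal lengths")
    return np.mean(arrays, axis=0)


@dataclass
class IVResult:
    """Per-step current-voltage table with interpolated reversal potential."""

    v: np.ndarray  # mV
    i: np.ndarray  # pA
    erev: float  # mV (nan when undefined)
    erev_defined: bool


def iv_extract(
    trace: CurrentTrace,
    protocol: VoltageProtocol | None = None,
    measure: Literal["peak", "steady", "tail-max"] = "steady",
) -> IVResult:
    """Per-sweep scalar current vs step voltage from a step-family protocol.

    'steady' averages the last 20% of the family step, 'peak' takes the
    extremum within the step, 'tail-max' the extremum of the following
    segment.  E_rev is the zero crossing of the I-V by linear interpolation
    between the bracketing grid points; monotone data without a sign change
    leave it undefined (flagged).
    """
    proto = protocol if protocol is not None else trace.protocol
    if proto is None or proto.family is None:
        raise ValueError("iv_extract needs a step-family protocol")
    seg = proto.family_segment
    t0, t1 = proto.segment_window(seg)
    times = trace.times()
    if measure == "tail-max":
        if seg + 1 >= len(proto.segments):
            raise ValueError("no segment after the family step for tail-max")
        t0, t1 = proto.segment_window(seg + 1)
        mask = (times >= t0) & (times < t1)
    elif measure == "steady":
        mask = (times >= t1 - 0.2 * (t1 - t0)) & (times < t1)
    else:
        mask = (times >= t0) & (times < t1)
    v = np.asarray(proto.family, dtype=float)
    i = np.empty(v.size)
    for k, sweep in enumerate(trace.sweeps):
        window = sweep[mask]
        if measure == "steady":
            i[k] = window.mean()
        else:
            i[k] = window[np.argmax(np.abs(window))]
    order = np.argsort(v)
    v_s, i_s = v[order], i[order]
    sign_change = np.flatnonzero(np.diff(np.sign(i_s)) != 0)
    crossings = [k for k in sign_change if i_s[k] != 0 or i_s[k + 1] != 0]
    if not crossings:
        return IVResult(v_s, i_s, math.nan, False)
    k = crossings[0]
    if i_s[k] == 0:
        erev = float(v_s[k])
    else:
        erev = float(v_s[k] - i_s[k] * (v_s[k + 1] - v_s[k]) / (i_s[k + 1] - i_s[k]))
    return IVResult(v_s, i_s, erev, True)


def current_density(i: float, capacitance: float) -> float:
    """Current density in pA/pF."""
    if capacitance is None or not capacitance > 0:
        raise ValueError("capacitance must be > 0 pF")
    return i / capacitance


def inactivation_rate(
    tail_amplitudes: Sequence[float],
    suprathreshold_time: Sequence[float],
) -> FitResult:
    """tau_inact from tail amplitude vs cumulative suprathreshold time.

    Fits B + A exp(-t/tau) to the (normalised) tail amplitudes of sweeps
    whose cumulative time above E_Ca is positive; tau is reported in the
    units of ``suprathreshold_time`` (seconds).  Invariant to amplitude
    rescaling.  Fewer than four suprathreshold sweeps: unconverged.
    """
    amp = np.abs(np.asarray(tail_amplitudes, dtype=float))
    t = np.asarray(suprathreshold_time, dtype=float)
    if amp.size != t.size:
        raise ValueError("amplitude and time arrays differ in length")
    mask = t > 0
    if mask.sum() < 4:
        return FitResult(
            "exponential", {}, math.nan, False, int(mask.sum()),
            "fewer than 4 suprathreshold sweeps",
        )
    amp, t = amp[mask], t[mask]
    scale = amp[0] if amp[0] != 0 else 1.0
    y = amp / scale
    spread = y.max() - y.min()
    if spread <= 1e-9:
        return FitResult(
            "exponential", {"B": float(y.mean()), "A": 0.0, "tau": math.nan},
            0.0, False, y.size, "amplitudes constant: tau unidentifiable",
        )
    tau0 = float(t[-1] / 3.0)
    try:
        popt, _ = curve_fit(
            _exp_model, t, y, p0=(0.0, y[0], tau0),
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return FitResult("exponential", {}, math.nan, False, y.size, f"fit failed: {exc}")
    resid = y - _exp_model(t, *popt)
    return FitResult(
        "exponential",
        {"B": float(popt[0]), "A": float(popt[1]), "tau": float(popt[2])},
        float(np.sqrt(np.mean(resid**2))), True, y.size,
    )
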