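"""Haemodynamic trace post-processing.

Cycle segmentation and averaging, transvalvular pressure difference,
ejection-window detection, mean transvalvular flow (Qmean) and pressure
drop (dp_mean), stroke volume, inter-cycle statistics and measurement
uncertainty bounds.

Conventions: integration is trapezoidal throughout; threshold crossings are
located by linear interpolation between samples, and an exact zero sample
counts as a crossing.  No filtering is applied beyond cycle averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import TimeTrace


@dataclass
class CycleEnsemble:
    """Per-cycle traces aligned to a common cycle time plus their mean/sd."""

    cycle_time: float
    cycles: list  # of TimeTrace on the common grid [0, T)
    mean_trace: TimeTrace = None
    sd_trace: TimeTrace = None

    def __post_init__(self):
        lengths = {len(c) for c in self.cycles}
        if len(lengths) > 1:
            raise ValueError("all member traces must have the same length")
        if self.mean_trace is None and self.cycles:
            vals = np.stack([c.value for c in self.cycles])
            t = self.cycles[0].t
            self.mean_trace = TimeTrace(t, vals.mean(axis=0))
            sd = vals.std(axis=0, ddof=1) if len(self.cycles) > 1 else np.zeros(vals.shape[1])
            self.sd_trace = TimeTrace(t, sd)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class HemoSummary:
    """Per-experiment haemodynamic summary (clinical units)."""

    q_mean: float  # mL/s
    q_mean_sd: float  # mL/s
    dp_mean: float  # mmHg
    stroke_volume: float  # mL
    ejection_window: tuple  # (t_start, t_end) s
    uncertainty_frac: float = 0.10
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ejection_window[0] >= self.ejection_window[1]:
            raise ValueError("ejection window must have t_start < t_end")
        if self.q_mean_sd < 0:
            raise ValueError("q_mean_sd must be non-negative")


def detect_periodic_start(trace: TimeTrace, cycle_time: float, rms_frac: float = 0.05) -> int:
    """First cycle index whose RMS difference to the next cycle drops below
    rms_frac of the signal range; returns a sample index.  Optional helper —
    callers normally supply the start index themselves."""
    n = int(round(cycle_time / trace.dt))
    n_cyc = len(trace) // n
    rng_ = np.ptp(trace.value)
    for k in range(n_cyc - 1):
        a = trace.value[k * n:(k + 1) * n]
        b = trace.value[(k + 1) * n:(k + 2) * n]
        if np.sqrt(np.mean((a - b) ** 2)) < rms_frac * rng_:
            return k * n
    return 0


def segment_cycles(trace: TimeTrace, cycle_time: float, start_index: int = 0) -> CycleEnsemble:
    """Cut a long trace into consecutive non-overlapping cycles of length T.

    A trailing partial cycle is discarded.  Fewer than two complete cycles
    after ``start_index`` is an error.
    """
    n = int(round(cycle_time / trace.dt))
    if n < 2:
        raise ValueError("cycle_time too short for the sampling rate")
    avail = len(trace) - start_index
    n_cyc = avail // n
    if n_cyc < 2:
        raise ValueError(f"need at least 2 full cycles, found {n_cyc}")
    t_local = trace.dt * np.arange(n)
    cycles = [TimeTrace(t_local, trace.value[start_index + k * n: start_index + (k + 1) * n].copy())
              for k in range(n_cyc)]
    return CycleEnsemble(cycle_time=cycle_time, cycles=cycles)


def pressure_difference(p_lv: TimeTrace, p_ao: TimeTrace) -> TimeTrace:
    """Transvalvular pressure difference dp(t) = pLV(t) - pAO(t), mmHg."""
    if not p_lv.same_grid(p_ao):
        raise ValueError("pressure traces are on different grids; resample explicitly first")
    return TimeTrace(p_lv.t.copy(), p_lv.value - p_ao.value, "mmHg", dict(p_lv.meta))


def periodic_extend(mean_trace: TimeTrace, n_cycles: int = 6) -> TimeTrace:
    """Repeat a one-cycle trace periodically over n_cycles."""
    n = len(mean_trace)
    dt = mean_trace.dt
    t = dt * np.arange(n * n_cycles)
    return TimeTrace(t, np.tile(mean_trace.value, n_cycles), mean_trace.units, dict(mean_trace.meta))


def _interp_crossing(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-sample time where y crosses zero between samples i and i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t[i])
    return float(t[i] - y0 * (t[i + 1] - t[i]) / (y1 - y0))


def ejection_window(q: TimeTrace, p_lv: TimeTrace, p_ao: TimeTrace) -> tuple[float, float]:
    """Ejection interval: from the first upward pLV > pAO crossing to the
    first subsequent time the flow drops below zero.

    If the flow never becomes negative within the trace the window falls
    back to the downward zero crossing of the pressure difference.
    """
    if not (q.same_grid(p_lv) and q.same_grid(p_ao)):
        raise ValueError("traces must share a common grid")
    dp = p_lv.value - p_ao.value
    up = np.where((dp[:-1] <= 0) & (dp[1:] > 0))[0]
    if len(up) == 0:
        if dp[0] > 0:
            t_start = float(q.t[0])
            i_start = 0
        else:
            raise ValueError("no pLV > pAO upward crossing found in the trace")
    else:
        i_start = int(up[0])
        t_start = _interp_crossing(q.t, dp, i_start)
    qv = q.value
    neg = np.where((qv[:-1] >= 0) & (qv[1:] < 0))[0]
    neg = neg[neg >= i_start]
    if len(neg) > 0:
        t_end = _interp_crossing(q.t, qv, int(neg[0]))
    else:
        down = np.where((dp[:-1] > 0) & (dp[1:] <= 0))[0]
        down = down[down >= i_start]
        if len(down) == 0:
            raise ValueError("no ejection end: flow never negative and dp never recrosses zero")
        t_end = _interp_crossing(q.t, dp, int(down[0]))
    return (t_start, t_end)


def _window_slice(trace: TimeTrace, window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    t0, t1 = window
    if not (trace.t[0] - trace.dt <= t0 < t1 <= trace.t[-1] + trace.dt):
        raise ValueError("window outside trace")
    if t1 - t0 <= 0:
        raise ValueError("zero-length window")
    # resample boundary values by linear interpolation so sub-sample windows
    # integrate consistently
    mask = (trace.t > t0) & (trace.t < t1)
    t = np.concatenate([[t0], trace.t[mask], [t1]])
    v = np.interp(t, trace.t, trace.value)
    return t, v


def q_mean(q: TimeTrace, window: tuple[float, float]) -> float:
    """Mean flow over the ejection window: trapezoidal integral / duration."""
    t, v = _window_slice(q, window)
    return float(np.trapezoid(v, t) / (window[1] - window[0]))


def stroke_volume(q: TimeTrace, window: tuple[float, float]) -> float:
    """Trapezoidal flow integral over the ejection window (mL for mL/s input)."""
    t, v = _window_slice(q, window)
    return float(np.trapezoid(v, t))


def dp_mean(dp: TimeTrace, cycle_time: float | None = None) -> float:
    """Mean pressure difference over the contiguous dp > 0 region.

    If ``cycle_time`` is given the trace is segmented first and the
    per-cycle means are averaged; otherwise the longest contiguous positive
    region of the trace is used (the longest, not the first, so measurement
    noise crossing zero cannot select a spurious blip).
    """
    if cycle_time is not None:
        ens = segment_cycles(dp, cycle_time)
        return float(np.mean([dp_mean(c) for c in ens.cycles]))
    v = dp.value
    if not np.any(v > 0):
        raise ValueError("pressure difference is nowhere positive")
    padded = np.concatenate([[0], (v > 0).astype(int), [0]])
    edges = np.diff(padded)
    starts, ends = np.where(edges == 1)[0], np.where(edges == -1)[0]
    k = int(np.argmax(ends - starts))
    i0, i1 = int(starts[k]), int(ends[k]) - 1
    t0 = dp.t[i0] if i0 == 0 else _interp_crossing(dp.t, v, i0 - 1)
    t1 = dp.t[i1] if i1 == len(v) - 1 else _interp_crossing(dp.t, v, i1)
    if t1 <= t0:
        return float(v[i0])
    t, vv = _window_slice(dp, (t0, t1))
    return float(np.trapezoid(vv, t) / (t1 - t0))


def inter_cycle_stats(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample standard deviation of a per-cycle metric."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no values")
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd


def uncertainty_bounds(value: float, frac: float = 0.10) -> tuple[float, float]:
    """Symmetric measurement-uncertainty interval value * (1 -+ frac)."""
    return (value * (1.0 - frac), value * (1.0 + frac))


def summarize(q: TimeTrace, p_lv: TimeTrace, p_ao: TimeTrace, cycle_time: float,
              start_index: int = 0, uncertainty_frac: float = 0.10) -> HemoSummary:
    """Full per-experiment summary: per-cycle Qmean/dp_mean statistics.

    Segments all three traces, computes the ejection window and metrics per
    cycle, and aggregates with :func:`inter_cycle_stats`.
    """
    q_ens = segment_cycles(q, cycle_time, start_index)
    lv_ens = segment_cycles(p_lv, cycle_time, start_index)
    ao_ens = segment_cycles(p_ao, cycle_time, start_index)
    qs, dps, svs = [], [], []
    window = None
    for qc, lc, ac in zip(q_ens.cycles, lv_ens.cycles, ao_ens.cycles):
        w = ejection_window(qc, lc, ac)
        window = window or w
        qs.append(q_mean(qc, w))
        svs.append(stroke_volume(qc, w))
        dpc = pressure_difference(lc, ac)
        dps.append(dp_mean(dpc))
    qm, qsd = inter_cycle_stats(np.array(qs))
    dpm, _ = inter_cycle_stats(np.array(dps))
    svm, _ = inter_cycle_stats(np.array(svs))
    return HemoSummary(q_mean=qm, q_mean_sd=qsd, dp_mean=dpm, stroke_volume=svm,
                       ejection_window=window, uncertainty_frac=uncertainty_frac)
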