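"""Per-trial detection of discharge onset and offset.

The single-trial pipeline mirrors standard practice for burst timing in
locomotor electrophysiology: spike times are converted to an
instantaneous frequency (1000/interspike interval, sample-and-hold on a
1-ms grid), low-pass filtered at 50 Hz with a fourth-order Butterworth
filter applied forward and backward (zero phase), and the onset of a
discharge change is the earliest point at which the filtered rate
deviates from the baseline mean by more than 2 SD of the baseline,
sustained for a minimum duration.  Baseline statistics come from the
window 2.5-3 s before the step over the obstacle.  The detected onset is
then mapped onto the gap trace to read off the distance-to-contact and
time-to-contact at that moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from gapclosure.task_kinematics import GapTrace

__all__ = [
    "RateTrace",
    "BaselineStats",
    "OnsetDetection",
    "instantaneous_frequency",
    "lowpass",
    "baseline_stats",
    "detect_onset",
    "detect_offset",
    "map_onset_to_gap",
    "detection_grid",
]

BASELINE_WINDOW = (-3000.0, -2500.0)  # ms before the step over the obstacle
SD_FLOOR = 1.0  # spk/s, fallback threshold for silent baselines


@dataclass
class RateTrace:
    """Firing rate (spk/s) on a uniform ms grid."""

    time: np.ndarray
    rate: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.time.shape != self.rate.shape:
            raise ValueError("time and rate must have the same shape")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0]):
                raise ValueError("rate trace requires a uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 1.0


@dataclass(frozen=True)
class BaselineStats:
    """Mean and SD of the pre-obstacle baseline rate; 2*sd is the detection threshold."""

    mean: float
    sd: float
    window: tuple[float, float] = BASELINE_WINDOW


@dataclass(frozen=True)
class OnsetDetection:
    """One detected change of discharge in a single trial."""

    onset: float  # ms
    direction: str  # 'increase' | 'decrease'
    flags: tuple[str, ...] = ()


def detection_grid(gap: GapTrace | None, t_stop: float = 2000.0) -> np.ndarray:
    """Default 1-ms analysis grid, from 3.5 s before the step over the
    obstacle (clipped to the gap-trace start) to ``t_stop``.

    3.5 s covers the baseline window with margin; the discharge
    modulation of interest happens within the last two step cycles.
    """
    return np.arange(BASELINE_WINDOW[0] - 500.0, t_stop + 1.0)


def instantaneous_frequency(spikes, grid: np.ndarray) -> RateTrace:
    """Sample-and-hold 1000/ISI rate on ``grid``.

    Each interspike interval (t_k, t_{k+1}] carries the constant value
    1000/(t_{k+1} - t_k); samples outside any interval are zero.  Fewer
    than two spikes yield an all-zero trace flagged ``'too_few_spikes'``.
    """
    times = np.asarray(getattr(spikes, "times", spikes), dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(times) < 2:
        return RateTrace(time=grid, rate=np.zeros_like(grid), flags=("too_few_spikes",))
    rate = np.zeros_like(grid)
    idx = np.searchsorted(times, grid, side="left")
    inside = (idx > 0) & (idx < len(times))
    isi = np.diff(times)
    rate[inside] = 1000.0 / isi[idx[inside] - 1]
    return RateTrace(time=grid, rate=rate)


def lowpass(trace: RateTrace, cutoff: float = 50.0, order: int = 4) -> RateTrace:
    """Zero-phase Butterworth low-pass (default 50 Hz, 4th order).

    ``filtfilt`` is used so the smoothed trace has no systematic lag that
    would bias onset times.
    """
    fs = 1000.0 / trace.dt
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz at or above Nyquist ({fs / 2.0} Hz)")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    smoothed = signal.sosfiltfilt(sos, trace.rate)
    return RateTrace(time=trace.time, rate=np.asarray(smoothed), flags=trace.flags)


def baseline_stats(trace: RateTrace, window: tuple[float, float] = BASELINE_WINDOW) -> BaselineStats:
    """Mean and population SD of the rate inside ``window``."""
    lo, hi = window
    if trace.time[0] > lo or trace.time[-1] < hi:
        raise ValueError(f"trace does not cover the baseline window {window}")
    sel = (trace.time >= lo) & (trace.time <= hi)
    seg = trace.rate[sel]
    return BaselineStats(mean=float(np.mean(seg)), sd=float(np.std(seg)), window=window)


def _first_sustained_run(mask: np.ndarray, n_sustain: int) -> int | None:
    """Index of the first True run of length >= n_sustain, else None."""
    if not mask.any():
        return None
    padded = np.concatenate([[0], mask.astype(int), [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for s, e in zip(starts, ends):
        if e - s >= n_sustain:
            return int(s)
    return None


def pooled_baseline_stats(
    traces: "list[RateTrace]", window: tuple[float, float] = BASELINE_WINDOW
) -> BaselineStats:
    """Baseline statistics pooled over the baseline windows of many trials.

    A single 500-ms window holds only a handful of interspike intervals
    at typical baseline rates, so its per-trial SD is wildly unstable;
    pooling the same window across a cell's trials gives a usable
    estimate of the same quantity.
    """
    segs = []
    for tr in traces:
        lo, hi = window
        if tr.time[0] > lo or tr.time[-1] < hi:
            raise ValueError(f"trace does not cover the baseline window {window}")
        sel = (tr.time >= lo) & (tr.time <= hi)
        segs.append(tr.rate[sel])
    pooled = np.concatenate(segs)
    return BaselineStats(mean=float(np.mean(pooled)), sd=float(np.std(pooled)), window=window)


def detect_onset(
    trace: RateTrace,
    stats: BaselineStats,
    sustain: float = 50.0,
    search_start: float | None = None,
    backtrack: bool = True,
) -> OnsetDetection | None:
    """Earliest sustained deviation beyond 2 SD of baseline.

    The search begins at the end of the baseline window (or at
    ``search_start``); the rate must stay beyond mean +/- 2*sd
    continuously for at least ``sustain`` ms.  Both increases and
    decreases count; the direction at the crossing is recorded.  With
    ``backtrack`` (default) the reported onset is moved back from the
    threshold crossing to the last preceding crossing of the baseline
    mean, removing the systematic delay of waiting for the rate to
    clear the threshold.  A zero baseline SD falls back to an absolute
    1 spk/s threshold (flagged).
    """
    flags: tuple[str, ...] = ()
    threshold = 2.0 * stats.sd
    if stats.sd == 0.0:
        threshold = SD_FLOOR
        flags = ("sd_floor",)
    start = stats.window[1] if search_start is None else search_start
    sel = trace.time >= start
    t = trace.time[sel]
    dev = trace.rate[sel] - stats.mean
    n_sustain = max(1, int(round(sustain / trace.dt)))
    i = _first_sustained_run(np.abs(dev) > threshold, n_sustain)
    if i is None:
        return None
    direction = "increase" if dev[i] > 0 else "decrease"
    if backtrack and i > 0:
        sign = 1.0 if direction == "increase" else -1.0
        below = np.nonzero(sign * dev[:i] <= 0.0)[0]
        if len(below):
            i = int(below[-1]) + 1
    return OnsetDetection(onset=float(t[i]), direction=direction, flags=flags)


def detect_offset(
    trace: RateTrace,
    stats: BaselineStats,
    after: float,
    sustain: float = 50.0,
) -> tuple[float, tuple[str, ...]]:
    """End of the discharge: first sustained return to within 2 SD of baseline
    after the post-onset peak.  If the rate never settles back before the
    trace ends, the trace end is returned with a ``'no_return'`` flag."""
    threshold = 2.0 * stats.sd if stats.sd > 0 else SD_FLOOR
    sel = trace.time >= after
    t = trace.time[sel]
    dev = np.abs(trace.rate[sel] - stats.mean)
    if len(t) == 0:
        raise ValueError("'after' beyond the end of the trace")
    peak_i = int(np.argmax(dev))
    t_peak = t[peak_i]
    sel2 = t >= t_peak
    n_sustain = max(1, int(round(sustain / trace.dt)))
    i = _first_sustained_run(dev[sel2] <= threshold, n_sustain)
    if i is None:
        return float(t[-1]), ("no_return",)
    return float(t[sel2][i]), ()


def fit_hinge_onset(
    trace: RateTrace,
    t_start: float = -2500.0,
    t_end: float | None = None,
    step: float = 10.0,
) -> float:
    """Breakpoint of a hinge (baseline + linear ramp) fit to a rate trace.

    Least-squares fit of ``rate = b + s * max(0, t - tau)`` over
    ``[t_start, t_end]`` (default: up to the trace maximum in that
    range), with ``tau`` scanned on a ``step``-ms grid.  On
    trial-averaged traces this localizes the population ramp onset
    without the bias a threshold or mean-crossing rule carries.
    """
    sel = trace.time >= t_start
    t = trace.time[sel]
    r = trace.rate[sel]
    if t_end is None:
        t_end = float(t[np.argmax(r)])
    sel2 = t <= t_end
    t, r = t[sel2], r[sel2]
    n = len(t)
    if n < 10:
        raise ValueError("hinge fit window too short")
    # suffix sums make the LS solution O(1) per candidate breakpoint
    sub = max(1, int(round(step / (t[1] - t[0]))))
    St = np.cumsum(t[::-1])[::-1]
    Stt = np.cumsum((t * t)[::-1])[::-1]
    Sr = np.cumsum(r[::-1])[::-1]
    Str = np.cumsum((t * r)[::-1])[::-1]
    Sy = float(r.sum())
    Syy = float(r @ r)
    j = np.arange(0, n - 5, sub)
    n_suf = n - 1 - j  # samples strictly after the breakpoint
    tau = t[j]
    sx = St[j + 1] - n_suf * tau
    sxx = Stt[j + 1] - 2.0 * tau * St[j + 1] + n_suf * tau * tau
    sxy = Str[j + 1] - tau * Sr[j + 1]
    det = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (n * sxy - sx * Sy) / det
        b = (Sy - s * sx) / n
        sse = (
            Syy
            + n * b * b
            + s * s * sxx
            + 2.0 * b * s * sx
            - 2.0 * b * Sy
            - 2.0 * s * sxy
        )
    sse = np.where(det <= 0, np.inf, sse)
    return float(tau[int(np.argmin(sse))])


def rising_mean_crossings(trace: RateTrace, mean: float, direction: str = "increase") -> np.ndarray:
    """Times where the trace crosses ``mean`` in the onset direction.

    For an activity increase these are upward crossings (candidate burst
    onsets on a smoothed trace); for a decrease, downward crossings.
    """
    dev = trace.rate - mean
    if direction == "decrease":
        dev = -dev
    up = np.nonzero((dev[:-1] <= 0.0) & (dev[1:] > 0.0))[0]
    return trace.time[up + 1]


def map_onset_to_gap(onset: float, gap: GapTrace) -> tuple[float, float]:
    """DTC (cm) and TTC (ms) at the detected onset, by linear interpolation."""
    return float(gap.dtc_at(onset)), float(gap.ttc_at(onset))
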