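"""Peri-event histograms, population ramps, and onset-to-peak slopes.

Single cells are summarized by peri-event histograms (PEHs) aligned to
the lead-limb flexor burst of the step over the obstacle; populations by
the average of normalized per-cell rates.  The population discharge
forms a ramp that peaks just before the step -- its onset and the slope
``(max rate - rate at onset) / (t_max - t_onset)`` quantify how the
approach signal sharpens when the obstacle accelerates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from gapclosure import onset_detection as od

__all__ = [
    "PEH",
    "PopulationTrace",
    "build_peh",
    "peh_rate_trace",
    "population_average",
    "ramp_slope",
    "population_onset",
]

PEH_WINDOW = (-3200.0, 2000.0)  # ms around the alignment event
PEH_BIN = 2.0  # ms


@dataclass
class PEH:
    """Trial-averaged firing rate in fixed-width bins around an event."""

    edges: np.ndarray  # ms, len n_bins + 1
    rate: np.ndarray  # spk/s per bin
    n_trials: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class PopulationTrace:
    """Mean normalized rate across cells on a common time grid."""

    time: np.ndarray
    rate: np.ndarray
    mode: str
    n_cells: int


def build_peh(
    spike_trains: Iterable,
    alignment_times: Sequence[float] | None = None,
    window: tuple[float, float] = PEH_WINDOW,
    bin_width: float = PEH_BIN,
) -> PEH:
    """Peri-event histogram from per-trial spike trains.

    ``alignment_times`` (one per trial, default all zero -- trials are
    already aligned to the lead-limb Br onset) are subtracted from the
    spike times; counts in ``bin_width``-ms bins are averaged across
    trials and divided by the bin width to yield spk/s.
    """
    trains = list(spike_trains)
    if not trains:
        raise ValueError("need at least one trial")
    if alignment_times is None:
        alignment_times = [0.0] * len(trains)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty PEH window")
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for train, t0 in zip(trains, alignment_times):
        times = np.asarray(getattr(train, "times", train), dtype=float) - t0
        counts += np.histogram(times, bins=edges)[0]
    rate = counts / len(trains) / (bin_width / 1000.0)
    return PEH(edges=edges, rate=rate, n_trials=len(trains))


def peh_rate_trace(peh: PEH, cutoff: float = 50.0) -> od.RateTrace:
    """PEH as a smoothed rate trace (same 50 Hz zero-phase filter as the
    single-trial pipeline)."""
    trace = od.RateTrace(time=peh.centers, rate=peh.rate)
    return od.lowpass(trace, cutoff=cutoff)


def population_average(
    pehs: Sequence[PEH],
    mode: str = "max_norm",
    cutoff: float = 50.0,
) -> PopulationTrace:
    """Average normalized rate across cells.

    ``max_norm`` scales every cell by the peak rate of the cell with the
    highest discharge, preserving relative amplitudes; ``zscore``
    standardizes each cell by its own mean and SD.  All-zero cells are
    excluded.
    """
    if len(pehs) < 2:
        raise ValueError("population average needs at least 2 cells")
    traces = [peh_rate_trace(p, cutoff) for p in pehs]
    grid = traces[0].time
    rates = [np.interp(grid, tr.time, tr.rate) for tr in traces]
    rates = [r for r in rates if np.any(r > 0)]
    if not rates:
        raise ValueError("all cells have zero rate")
    R = np.vstack(rates)
    if mode == "max_norm":
        R = R / R.max()
    elif mode == "zscore":
        mu = R.mean(axis=1, keepdims=True)
        sd = R.std(axis=1, keepdims=True)
        R = (R - mu) / np.where(sd > 0, sd, 1.0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return PopulationTrace(time=grid, rate=R.mean(axis=0), mode=mode, n_cells=len(rates))


def population_onset(trace: PopulationTrace, fraction: float = 0.2) -> float:
    """Onset of the population ramp, amplitude-referenced.

    The last upward crossing, before the peak, of ``baseline +
    fraction * (peak - baseline)``, with the baseline taken from the
    pre-obstacle window.  Referencing the threshold to the ramp's own
    amplitude (rather than to the baseline SD, which shrinks with the
    number of averaged trials) makes population onsets comparable
    across conditions and population sizes.
    """
    rt = od.RateTrace(time=trace.time, rate=trace.rate)
    stats = od.baseline_stats(rt)
    t, r = rt.time, rt.rate
    # the discharge of interest peaks near the step over the obstacle
    search = np.nonzero(t <= 500.0)[0]
    i_peak = int(search[np.argmax(r[search])])
    level = stats.mean + fraction * (r[i_peak] - stats.mean)
    pre = r[: i_peak + 1]
    up = np.nonzero((pre[:-1] <= level) & (pre[1:] > level))[0]
    if len(up) == 0:
        return od.fit_hinge_onset(rt, t_start=od.BASELINE_WINDOW[1])
    return float(t[up[-1] + 1])


def ramp_slope(
    trace: PopulationTrace | od.RateTrace,
    onset: float,
    search_end: float = 500.0,
) -> float:
    """Onset-to-peak slope of an averaged trace, in spk/s^2.

    ``(max rate - rate at onset) / (t_max - t_onset)``, with the maximum
    taken after the onset (up to ``search_end``).  A maximum at the
    onset itself yields slope 0.
    """
    t = np.asarray(trace.time, dtype=float)
    r = np.asarray(trace.rate, dtype=float)
    if onset < t[0] or onset > t[-1]:
        raise ValueError("onset outside trace")
    sel = (t >= onset) & (t <= search_end)
    if not sel.any():
        raise ValueError("no samples after onset")
    i_max = int(np.argmax(r[sel]))
    t_max = float(t[sel][i_max])
    r_max = float(r[sel][i_max])
    r_onset = float(np.interp(onset, t, r))
    dt_s = (t_max - onset) / 1000.0
    if dt_s <= 0:
        return 0.0
    return (r_max - r_onset) / dt_s
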