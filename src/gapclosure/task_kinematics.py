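"""Cat-obstacle gap kinematics on a treadmill.

A cat walks on a treadmill at constant belt speed while an obstacle,
mounted on a second belt, advances toward it.  The gap between the cat's
head and the obstacle closes over several step cycles and the animal
steps over the obstacle with one forelimb (the *lead* limb).  Two
quantities describe the closing gap at any instant:

* **DTC** (distance-to-contact, cm) -- the remaining distance between
  head marker and obstacle;
* **TTC** (time-to-contact, ms) -- the time until the obstacle reaches
  the cat, given the future closure-speed profile.

When the obstacle moves at the belt speed (*matched* task) DTC and TTC
are proportional through a single constant.  Slowing the obstacle
(*visual dissociation* task) changes that constant, so a neuron whose
discharge onset tracks a fixed distance and one that tracks a fixed time
become distinguishable.  Ramp accelerations of the obstacle, triggered
off a forelimb flexor burst, perturb the gap late in the approach.

Conventions used throughout the package: time is in ms with ``t = 0`` at
the lead-limb flexor (Br) burst onset of the step over the obstacle and
negative times before it; distances in cm; speeds accepted in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AccelerationProfile",
    "DriftModel",
    "TaskConfig",
    "GapTrace",
    "GaitEvent",
    "GaitTimeline",
    "obstacle_speed_at",
    "ttc_at_distance",
    "gait_timeline",
    "gap_trace",
]

#: m/s -> cm/ms
MS_TO_CM_PER_MS = 0.1

Limb = Literal["left", "right"]
TriggerCondition = Literal["1L", "2L", "1R", "2R"]


@dataclass(frozen=True)
class AccelerationProfile:
    """Symmetric ramp acceleration of the obstacle.

    The obstacle speeds up linearly from ``v_start`` to ``v_peak`` over
    ``ramp_duration`` ms and (by default) decelerates symmetrically back,
    for a total episode of ``2 * ramp_duration`` ms.  The episode begins
    ``trigger_delay`` ms after the onset of the designated contralateral
    or ipsilateral Br burst one or two steps before the step over the
    obstacle (conditions 1L, 2L, 1R, 2R).
    """

    v_start: float = 0.3  # m/s
    v_peak: float = 0.65  # m/s
    ramp_duration: float = 450.0  # ms
    symmetric_decrease: bool = True
    trigger_condition: TriggerCondition = "1L"
    trigger_delay: float = 200.0  # ms after the designated Br onset

    def __post_init__(self) -> None:
        if self.v_peak <= self.v_start:
            raise ValueError("v_peak must exceed v_start")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")

    @property
    def episode_duration(self) -> float:
        """Total duration of the speed perturbation in ms."""
        return 2.0 * self.ramp_duration if self.symmetric_decrease else self.ramp_duration


@dataclass(frozen=True)
class DriftModel:
    """First-order autoregressive fore-aft drift of the cat on the belt.

    ``amplitude_cm`` is the stationary SD of the positional fluctuation,
    ``correlation_ms`` its correlation time.  Zero amplitude disables
    drift.
    """

    amplitude_cm: float = 3.0
    correlation_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.amplitude_cm < 0:
            raise ValueError("amplitude_cm must be >= 0")
        if self.correlation_ms <= 0:
            raise ValueError("correlation_ms must be positive")


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and speeds of one locomotor task.

    Defaults are the matched task: belt and obstacle both at 0.45 m/s,
    obstacles 3 m apart, 10 cm in cross-section, visible from ~2 m.
    The visual dissociation task slows the obstacle to 0.3 m/s.
    """

    treadmill_speed: float = 0.45  # m/s
    obstacle_speed: float = 0.45  # m/s
    obstacle_spacing: float = 3.0  # m
    obstacle_diameter: float = 10.0  # cm
    visibility_distance: float = 2.0  # m
    acceleration: AccelerationProfile | None = None
    step_period: float = 500.0  # ms between successive (alternating) Br onsets
    drift: DriftModel | None = None

    def __post_init__(self) -> None:
        if self.treadmill_speed <= 0 or self.obstacle_speed <= 0:
            raise ValueError("speeds must be positive")
        if self.step_period <= 0:
            raise ValueError("step_period must be positive")
        if self.visibility_distance > self.obstacle_spacing:
            raise ValueError("visibility_distance must not exceed obstacle_spacing")


GaitEvent = tuple[float, str, str]  # (time ms, limb, 'Br_onset' | 'Br_offset')


@dataclass
class GaitTimeline:
    """Ordered forelimb flexor (Br) burst events for one approach."""

    events: list[GaitEvent]
    lead_limb: Limb

    def br_onsets(self, limb: Limb | None = None) -> np.ndarray:
        """Onset times (ms, ascending), optionally for one limb."""
        t = [e[0] for e in self.events if e[2] == "Br_onset" and (limb is None or e[1] == limb)]
        return np.asarray(sorted(t), dtype=float)

    def br_offsets(self, limb: Limb | None = None) -> np.ndarray:
        t = [e[0] for e in self.events if e[2] == "Br_offset" and (limb is None or e[1] == limb)]
        return np.asarray(sorted(t), dtype=float)

    def acceleration_trigger_time(self, profile: AccelerationProfile) -> float:
        """Episode start time implied by the profile's trigger condition.

        ``nL``/``nR`` selects the n-th most recent left/right Br onset
        strictly before t = 0; the episode starts ``trigger_delay`` ms
        after that burst onset.
        """
        n = int(profile.trigger_condition[0])
        limb: Limb = "left" if profile.trigger_condition[1] == "L" else "right"
        onsets = self.br_onsets(limb)
        before = onsets[onsets < 0.0]
        if len(before) < n:
            raise ValueError(
                f"timeline has only {len(before)} {limb} Br onsets before t=0; "
                f"condition {profile.trigger_condition} needs {n}"
            )
        return float(before[-n] + profile.trigger_delay)


@dataclass
class GapTrace:
    """Time-indexed DTC/TTC for one approach to the obstacle.

    ``time`` is a uniform 1-ms grid ending at t = 0 (the lead-limb Br
    onset of the step over the obstacle); ``closure_speed`` is in m/s.
    """

    time: np.ndarray  # ms
    dtc: np.ndarray  # cm
    ttc: np.ndarray  # ms
    closure_speed: np.ndarray  # m/s

    def dtc_at(self, t: float | np.ndarray) -> float | np.ndarray:
        self._check_cover(t)
        return np.interp(t, self.time, self.dtc)

    def ttc_at(self, t: float | np.ndarray) -> float | np.ndarray:
        self._check_cover(t)
        return np.interp(t, self.time, self.ttc)

    def _check_cover(self, t) -> None:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.time[0]) or np.any(t > self.time[-1]):
            raise ValueError(
                f"time {t} outside gap trace range [{self.time[0]}, {self.time[-1]}] ms"
            )


def obstacle_speed_at(
    t: float | np.ndarray,
    profile: AccelerationProfile,
    t_trigger: float,
) -> float | np.ndarray:
    """Obstacle speed (m/s) at time ``t`` for a ramp episode starting at ``t_trigger``.

    Piecewise linear: ``v_start`` before the trigger, linear rise to
    ``v_peak`` over ``ramp_duration``, symmetric linear fall back, then
    ``v_start`` again.
    """
    t = np.asarray(t, dtype=float)
    tau = t - t_trigger
    d = profile.ramp_duration
    rise = profile.v_start + (profile.v_peak - profile.v_start) * tau / d
    if profile.symmetric_decrease:
        fall = profile.v_peak - (profile.v_peak - profile.v_start) * (tau - d) / d
        v = np.select(
            [tau <= 0, tau <= d, tau <= 2 * d],
            [profile.v_start, rise, fall],
            default=profile.v_start,
        )
    else:
        v = np.select(
            [tau <= 0, tau <= d], [profile.v_start, rise], default=profile.v_peak
        )
    return float(v) if v.ndim == 0 else v


def ttc_at_distance(dtc: float, closure_speed: float) -> float:
    """Time-to-contact (ms) at distance ``dtc`` (cm) closing at ``closure_speed`` (m/s).

    At the matched closure speed of 0.45 m/s a 45 cm gap corresponds to
    1000 ms; slowing the obstacle to 0.3 m/s stretches the same 45 cm to
    1500 ms -- the dissociation the two constant-speed tasks exploit.
    """
    if closure_speed <= 0:
        raise ValueError("TTC undefined for non-positive closure speed")
    if dtc < 0:
        raise ValueError("dtc must be >= 0")
    return dtc / (closure_speed * MS_TO_CM_PER_MS)


def gait_timeline(
    config: TaskConfig,
    n_steps: int = 12,
    jitter_sd: float = 0.0,
    lead_limb: Limb = "left",
    seed: int | np.random.Generator | None = None,
    duty_fraction: float = 0.5,
    max_retries: int = 100,
) -> GaitTimeline:
    """Alternating left/right Br burst timeline ending with the lead limb at t = 0.

    Onsets are spaced ``config.step_period`` ms apart with optional
    Gaussian jitter (the t = 0 lead-limb onset is the alignment anchor
    and is never jittered); each burst's offset follows its onset by
    ``duty_fraction * step_period`` ms.  Jitter draws that break the
    strict ordering of events are resampled up to ``max_retries`` times.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    period = config.step_period
    other: Limb = "right" if lead_limb == "left" else "left"
    base = -period * np.arange(n_steps)[::-1]  # ascending, last at 0
    limbs = [lead_limb if (n_steps - 1 - i) % 2 == 0 else other for i in range(n_steps)]
    for _ in range(max_retries):
        onsets = base.copy()
        if jitter_sd > 0:
            onsets[:-1] = onsets[:-1] + rng.normal(0.0, jitter_sd, size=n_steps - 1)
        if np.all(np.diff(onsets) > 0):
            break
    else:
        raise RuntimeError("could not draw a monotone gait timeline; reduce jitter_sd")
    burst = duty_fraction * period
    events: list[GaitEvent] = []
    for t0, limb in zip(onsets, limbs):
        events.append((float(t0), limb, "Br_onset"))
        events.append((float(t0 + burst), limb, "Br_offset"))
    events.sort(key=lambda e: e[0])
    return GaitTimeline(events=events, lead_limb=lead_limb)


def _drift_position(
    n: int, drift: DriftModel, rng: np.random.Generator, coarse_ms: float = 100.0
) -> np.ndarray:
    """Stationary AR(1) positional fluctuation, interpolated to the 1-ms grid.

    The process is sampled on a coarse grid (default 100 ms) and linearly
    interpolated, so the implied drift velocity stays small compared with
    the obstacle speed -- a slowly wandering animal, not ms-scale tremor.
    """
    coarse_ms = min(coarse_ms, drift.correlation_ms / 2.0)
    m = int(np.ceil(n / coarse_ms)) + 2
    a = float(np.exp(-coarse_ms / drift.correlation_ms))
    sigma_innov = drift.amplitude_cm * np.sqrt(1.0 - a * a)
    xc = np.empty(m)
    xc[0] = rng.normal(0.0, drift.amplitude_cm)
    eps = rng.normal(0.0, sigma_innov, size=m - 1)
    for k in range(1, m):
        xc[k] = a * xc[k - 1] + eps[k - 1]
    t_coarse = np.arange(m) * coarse_ms
    return np.interp(np.arange(n, dtype=float), t_coarse, xc)


def gap_trace(
    config: TaskConfig,
    timeline: GaitTimeline,
    initial_dtc: float = 200.0,
    seed: int | np.random.Generator | None = None,
    crossing_offset: float = 0.0,
    max_duration: float = 60_000.0,
) -> GapTrace:
    """DTC(t)/TTC(t) on a 1-ms grid, anchored so DTC(0) = ``crossing_offset``.

    The trace is built backward from the step over the obstacle: DTC at
    t = 0 equals the (usually ~0) crossing offset and grows backward in
    time by integrating the closure speed -- obstacle speed from the
    task's (possibly accelerating) profile plus the derivative of the
    cat's fore-aft drift.  TTC at each sample is the forward time until
    DTC first reaches zero under the realized future trajectory,
    extrapolated at the final closure speed if the offset is positive.

    Raises if ``initial_dtc`` is not reached within ``max_duration`` ms
    of backward integration.
    """
    if initial_dtc <= crossing_offset:
        raise ValueError("initial_dtc must exceed crossing_offset")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    v_floor = config.obstacle_speed
    if config.acceleration is not None:
        v_floor = min(v_floor, config.acceleration.v_start)
    horizon = min(max_duration, 2.5 * initial_dtc / (v_floor * MS_TO_CM_PER_MS))
    n_max = int(horizon) + 1
    t_full = -np.arange(n_max, dtype=float)[::-1]  # [-max_duration, ..., 0]

    if config.acceleration is not None:
        t_trig = timeline.acceleration_trigger_time(config.acceleration)
        v_obs = np.asarray(obstacle_speed_at(t_full, config.acceleration, t_trig))
    else:
        v_obs = np.full(n_max, config.obstacle_speed)

    drift_v = np.zeros(n_max)
    if config.drift is not None and config.drift.amplitude_cm > 0:
        x = _drift_position(n_max, config.drift, rng)
        # cat moving toward the obstacle adds to the closure speed
        drift_v[1:] = np.diff(x) / MS_TO_CM_PER_MS / 1.0  # cm/ms -> m/s
    closure = v_obs + drift_v  # m/s

    # dtc(t) = offset + integral_t^0 closure(s) ds  (backward accumulation)
    step_cm = closure * MS_TO_CM_PER_MS  # cm advanced per 1-ms sample
    dtc = crossing_offset + np.concatenate(
        [np.cumsum(step_cm[:0:-1])[::-1], [0.0]]
    )
    if dtc[0] < initial_dtc:
        raise ValueError(
            f"DTC never reaches {initial_dtc} cm within {max_duration} ms of backward integration"
        )
    # last sample still at or above initial_dtc (robust to drift wiggles)
    start = int(np.nonzero(dtc >= initial_dtc)[0][-1])
    start = min(start, n_max - 2)
    t = t_full[start:]
    dtc = dtc[start:]
    closure = closure[start:]

    ttc = _ttc_from_trajectory(t, dtc, closure[-1])
    return GapTrace(time=t, dtc=dtc, ttc=ttc, closure_speed=closure)


def _ttc_from_trajectory(t: np.ndarray, dtc: np.ndarray, v_end: float) -> np.ndarray:
    """Forward time until DTC first reaches 0, per sample.

    Uses the realized trajectory; beyond the trace end the gap is
    extrapolated at ``v_end`` (m/s), so a positive crossing offset still
    yields a finite TTC.
    """
    n = len(t)
    v_end_cm = max(v_end * MS_TO_CM_PER_MS, 1e-12)
    end_cross = t[-1] + max(dtc[-1], 0.0) / v_end_cm

    pos = dtc > 0.0
    if pos[:-1].all():
        # monotone-positive fast path: single crossing at (or beyond) the end
        cross = end_cross if pos[-1] else float(
            t[-2] + (t[-1] - t[-2]) * dtc[-2] / (dtc[-2] - dtc[-1])
        )
        ttc = cross - t
        ttc[~pos] = 0.0
        return ttc

    ttc = np.zeros(n)
    cross = end_cross
    for i in range(n - 1, -1, -1):
        if dtc[i] <= 0.0:
            cross = t[i]
            ttc[i] = 0.0
            continue
        if i < n - 1 and dtc[i + 1] <= 0.0 < dtc[i]:
            frac = dtc[i] / (dtc[i] - dtc[i + 1])
            cross = t[i] + frac * (t[i + 1] - t[i])
        ttc[i] = cross - t[i]
    return ttc
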