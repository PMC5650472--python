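"""Integrate-to-threshold model of lead-limb selection.

A conceptual model of how a gap-closure signal could choose which
forelimb steps over the obstacle first.  On each side of the brain a
ramp, rising as the obstacle approaches (starting 60 cm out), is summed
with a periodic limb-state gate that is high near the end of that
limb's stance phase.  Whichever side's summed signal crosses a
threshold first selects its limb.  Because the threshold exceeds either
signal alone, the crossing requires coincidence of an advanced ramp and
an appropriate limb state -- so the selected limb depends on the gait
phase at which the obstacle arrives, and a late acceleration of the
obstacle, which shifts arrival by about half a step cycle, reverses the
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from gapclosure.task_kinematics import (
    MS_TO_CM_PER_MS,
    AccelerationProfile,
    GapTrace,
    obstacle_speed_at,
)

__all__ = [
    "LimbModelConfig",
    "limb_state_signal",
    "approach_trace",
    "select_limb",
    "acceleration_reversal_experiment",
    "phase_sweep",
]


@dataclass(frozen=True)
class LimbModelConfig:
    """Parameters of the threshold model.

    The ramp rises linearly from 0 at ``ramp_start_distance`` to
    ``ramp_peak`` at contact.  Each limb's gate is ``gate_amplitude``
    during the last ``gate_duty`` fraction of its cycle (end of stance,
    just before its flexor burst) and 0 otherwise; the two limbs are in
    antiphase.  ``threshold`` defaults to 90% of (ramp peak + gate
    amplitude), so neither signal alone can cross it.  ``phase_at_start``
    is the left limb's cycle fraction when the obstacle is at the ramp
    start distance.
    """

    ramp_start_distance: float = 60.0  # cm
    ramp_peak: float = 1.0
    gate_amplitude: float = 1.0
    gate_duty: float = 0.25  # fraction of the cycle, end of stance
    threshold: float | None = None  # default 0.9 * (ramp_peak + gate_amplitude)
    step_period: float = 500.0  # ms between alternating flexor bursts
    closure_speed: float = 0.3  # m/s, unperturbed obstacle speed
    phase_at_start: float = 0.0  # left-limb cycle fraction at ramp start

    def __post_init__(self) -> None:
        if not (0 < self.gate_duty < 1):
            raise ValueError("gate_duty must lie in (0, 1)")
        if self.ramp_start_distance <= 0 or self.step_period <= 0:
            raise ValueError("distances and periods must be positive")
        theta = self.effective_threshold
        if theta <= max(self.ramp_peak, self.gate_amplitude):
            raise ValueError(
                "threshold must exceed both the ramp peak and the gate amplitude "
                "so that crossing requires their coincidence"
            )

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return 0.9 * (self.ramp_peak + self.gate_amplitude)

    @property
    def cycle(self) -> float:
        """Full step-cycle duration (ms): two alternating flexor bursts."""
        return 2.0 * self.step_period


def limb_state_signal(t: np.ndarray, config: LimbModelConfig) -> dict[str, np.ndarray]:
    """Periodic end-of-stance gates for both limbs.

    ``t = 0`` is the moment the obstacle crosses the ramp start
    distance, at left-limb phase ``config.phase_at_start``.  The gate is
    high during the last ``gate_duty`` of each limb's cycle; limbs are
    half a cycle apart.
    """
    t = np.asarray(t, dtype=float)
    out = {}
    for limb, offset in (("left", 0.0), ("right", 0.5)):
        phase = (config.phase_at_start + offset + t / config.cycle) % 1.0
        out[limb] = np.where(phase >= 1.0 - config.gate_duty, config.gate_amplitude, 0.0)
    return out


def approach_trace(
    config: LimbModelConfig,
    accel: AccelerationProfile | None = None,
    accel_onset: float | None = None,
    dt: float = 1.0,
    max_duration: float = 60_000.0,
) -> GapTrace:
    """Forward-simulated gap from the ramp start distance to contact.

    Unlike the event-anchored traces of the task-kinematics module, the
    model needs the *arrival phase* to be free: the obstacle starts at
    ``ramp_start_distance`` at t = 0 and advances at the unperturbed
    closure speed, optionally perturbed by a ramp acceleration episode
    beginning ``accel_onset`` ms into the approach.  Accelerations
    therefore shift the contact time relative to the (fixed) gait
    rhythm.
    """
    n = int(max_duration / dt)
    t = np.arange(n) * dt
    if accel is not None:
        onset = 0.0 if accel_onset is None else accel_onset
        v = np.asarray(obstacle_speed_at(t, accel, onset))
    else:
        v = np.full(n, config.closure_speed)
    dtc = config.ramp_start_distance - np.concatenate(
        [[0.0], np.cumsum(v[:-1] * MS_TO_CM_PER_MS * dt)]
    )
    hit = np.nonzero(dtc <= 0.0)[0]
    if len(hit) == 0:
        raise ValueError("obstacle never reaches the cat within max_duration")
    end = int(hit[0]) + 1
    t, dtc, v = t[:end], np.maximum(dtc[:end], 0.0), v[:end]
    ttc = np.zeros(end)
    ttc[:-1] = t[-1] - t[:-1]
    return GapTrace(time=t, dtc=dtc, ttc=ttc, closure_speed=v)


def select_limb(
    gap: GapTrace, config: LimbModelConfig
) -> tuple[str, float]:
    """First threshold crossing of ramp + gate; returns (limb, time).

    The ramp is mapped from distance: 0 at ``ramp_start_distance``,
    ``ramp_peak`` at contact.  Ties at the same sample resolve to the
    left (contralateral) limb, a documented convention.  Raises if
    neither summed signal reaches the threshold before contact.
    """
    t = gap.time
    ramp = config.ramp_peak * np.clip(
        1.0 - gap.dtc / config.ramp_start_distance, 0.0, 1.0
    )
    gates = limb_state_signal(t, config)
    theta = config.effective_threshold
    crossing: dict[str, float] = {}
    for limb in ("left", "right"):
        above = np.nonzero(ramp + gates[limb] >= theta)[0]
        if len(above):
            crossing[limb] = float(t[above[0]])
    if not crossing:
        raise ValueError("threshold unreachable before contact")
    best = min(crossing.values())
    winners = [limb for limb in ("left", "right") if crossing.get(limb) == best]
    return winners[0], best  # 'left' wins exact ties


def acceleration_reversal_experiment(
    config: LimbModelConfig,
    accel: AccelerationProfile | None = None,
    accel_onset: float | None = None,
) -> dict:
    """Does a late obstacle acceleration flip the selected lead limb?

    Runs the model on the unperturbed approach and on the same approach
    with a ramp acceleration episode (default profile, applied late: one
    step cycle before the unperturbed contact unless ``accel_onset``
    says otherwise).  The full episode closes an extra ~15.75 cm --
    about half a step cycle at the unperturbed speed -- so a late
    acceleration shifts the arrival phase by roughly half a cycle and
    reverses the selection.
    """
    accel = accel or AccelerationProfile()
    base_gap = approach_trace(config)
    if accel_onset is None:
        accel_onset = float(base_gap.time[-1]) - config.cycle
    accel_gap = approach_trace(config, accel=accel, accel_onset=accel_onset)
    limb_base, t_base = select_limb(base_gap, config)
    limb_accel, t_accel = select_limb(accel_gap, config)
    return {
        "baseline_limb": limb_base,
        "baseline_time": t_base,
        "accel_limb": limb_accel,
        "accel_time": t_accel,
        "accel_onset": accel_onset,
        "reversal": limb_base != limb_accel,
    }


def phase_sweep(
    config: LimbModelConfig,
    n_phases: int = 64,
    accel: AccelerationProfile | None = None,
    accel_onset: float | None = None,
) -> list[dict]:
    """Selected limb as a function of gait phase at ramp start.

    Sweeping the phase over one full cycle should show exactly two
    selection regimes (one left-to-right and one right-to-left
    transition): the model is a phase comparator between gap closure
    and the locomotor rhythm.
    """
    gap = approach_trace(config, accel=accel, accel_onset=accel_onset)
    rows = []
    for phase in np.linspace(0.0, 1.0, n_phases, endpoint=False):
        cfg = replace(config, phase_at_start=float(phase))
        limb, t_cross = select_limb(gap, cfg)
        rows.append({"phase": float(phase), "limb": limb, "crossing_time": t_cross})
    return rows
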