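"""Labelled synthetic spike trains with DTC/TTC tuning structure.

Each synthetic cell carries a ground-truth category: its discharge ramp
begins when the gap to the obstacle crosses a cell-specific trigger,
expressed either as a distance (DTC cells, 20-40 cm) or a time
(TTC cells, 300-1000 ms), with trial-to-trial Gaussian jitter of the
onset.  The ramp rises linearly to a peak just at the lead-limb flexor
burst of the step over the obstacle (t = 0) and decays exponentially
after it, whichever limb leads.  Spikes are drawn from the resulting
rate envelope as an inhomogeneous Poisson process with a refractory gap.

Because every trial retains the injected onset time and every cell its
category, the downstream detection/classification pipeline can be scored
against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from gapclosure.onset_detection import RateTrace
from gapclosure.task_kinematics import (
    AccelerationProfile,
    GaitTimeline,
    GapTrace,
    TaskConfig,
    gait_timeline,
    gap_trace,
)

__all__ = [
    "CellSpec",
    "SpikeTrain",
    "SyntheticTrial",
    "SessionDesign",
    "Session",
    "rate_envelope",
    "sample_spikes",
    "generate_session",
    "make_population",
]

Category = Literal["DTC", "TTC", "BOTH", "NONE", "STEP_RELATED"]
Task = Literal[
    "matched", "visual_dissociation", "accel_1L", "accel_2L", "accel_1R", "accel_2R", "unobstructed"
]

ACCEL_TASKS = ("accel_1L", "accel_2L", "accel_1R", "accel_2R")


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth tuning parameters of one synthetic cell.

    ``trigger_dtc_cm`` / ``trigger_ttc_ms`` hold the gap value at which
    the discharge ramp begins; DTC cells use the distance trigger, TTC
    cells the time trigger, BOTH cells whichever crosses first.  NONE
    cells ramp at a task-independent time with large jitter, and
    STEP_RELATED cells modulate with every step cycle instead of
    ramping.  ``tonic_vd_gain`` > 1 adds a tonic elevation of the
    pre-onset rate in the visual dissociation task.
    """

    cell_id: str
    category: Category = "DTC"
    trigger_dtc_cm: float | None = 30.0
    trigger_ttc_ms: float | None = None
    onset_jitter_sd: float = 150.0  # ms; plausible range ~120-230
    baseline_rate: float = 10.0  # spk/s
    peak_rate: float = 60.0  # spk/s
    peak_time: float = 0.0  # ms relative to lead-limb Br onset
    decay_time: float = 300.0  # ms, exponential decay constant after the peak
    tonic_vd_gain: float = 1.0

    def __post_init__(self) -> None:
        if not (self.peak_rate > self.baseline_rate >= 0):
            raise ValueError("need peak_rate > baseline_rate >= 0")
        if self.category in ("DTC", "BOTH") and self.trigger_dtc_cm is None:
            raise ValueError(f"{self.category} cell needs trigger_dtc_cm")
        if self.category in ("TTC", "BOTH") and self.trigger_ttc_ms is None:
            raise ValueError(f"{self.category} cell needs trigger_ttc_ms")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in ms; strictly increasing with >= 1 ms gaps."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SyntheticTrial:
    """One approach to (and step over) the obstacle for one cell.

    ``trial_seed`` is the per-trial child seed all of the trial's
    randomness (gait jitter, drift, envelope jitter, spikes) derives
    from, so a stored trial can be regenerated exactly.
    """

    trial_id: str
    cell_id: str
    task: Task
    lead_limb: str
    gait: GaitTimeline
    spikes: SpikeTrain
    gap: GapTrace | None = None  # absent for unobstructed steps
    truth_onset: float | None = None  # injected envelope onset, ms
    trial_seed: int | None = None
    initial_dtc: float | None = None


@dataclass(frozen=True)
class SessionDesign:
    """Trial-count plan for one cell's recording session.

    Defaults follow the recording protocol: ~10 steps over the obstacle
    per lead limb in the matched task, ~5 per limb after slowing the
    obstacle, 3 steps per acceleration condition, and interspersed
    unobstructed steps, for 62 trials per cell in total.
    """

    n_matched_per_lead: int = 10
    n_vd_per_lead: int = 5
    n_accel_per_condition: int = 3
    accel_conditions: Sequence[str] = ("1L", "2L", "1R", "2R")
    n_unobstructed: int = 20

    @property
    def n_trials(self) -> int:
        return (
            2 * self.n_matched_per_lead
            + 2 * self.n_vd_per_lead
            + self.n_accel_per_condition * len(self.accel_conditions)
            + self.n_unobstructed
        )

    def meets_inclusion(self) -> bool:
        """At least five unobstructed steps and three per acceleration condition."""
        return self.n_unobstructed >= 5 and (
            not self.accel_conditions or self.n_accel_per_condition >= 3
        )


@dataclass
class Session:
    """A generated dataset: cell specs plus their labelled trials."""

    cells: list[CellSpec]
    trials: dict[str, list[SyntheticTrial]]
    design: SessionDesign
    base_config: TaskConfig
    seed: int | None = None
    meets_inclusion: bool = True

    def trials_for(self, cell_id: str, task: str | None = None) -> list[SyntheticTrial]:
        out = self.trials[cell_id]
        return out if task is None else [t for t in out if t.task == task]


# ---------------------------------------------------------------------------
# rate envelopes


def _trigger_crossing(spec: CellSpec, gap: GapTrace) -> float | None:
    """First time the cell's trigger is crossed, or None if never."""
    candidates: list[float] = []
    if spec.category in ("DTC", "BOTH"):
        idx = np.nonzero(gap.dtc <= spec.trigger_dtc_cm)[0]
        if len(idx):
            candidates.append(float(gap.time[idx[0]]))
    if spec.category in ("TTC", "BOTH"):
        idx = np.nonzero(gap.ttc <= spec.trigger_ttc_ms)[0]
        if len(idx):
            candidates.append(float(gap.time[idx[0]]))
    return min(candidates) if candidates else None


def rate_envelope(
    spec: CellSpec,
    trial: SyntheticTrial,
    seed: int | np.random.Generator | None = None,
    t_stop: float = 2000.0,
) -> tuple[RateTrace, float | None]:
    """Firing-rate envelope for one trial, plus the injected onset time.

    Baseline until the (jittered) trigger crossing, then a linear ramp
    to ``peak_rate`` at ``peak_time`` and an exponential decay back to
    baseline.  NONE cells ramp at a task-independent time with 400 ms
    jitter; STEP_RELATED cells modulate sinusoidally with the step
    cycle, peaking at each lead-limb Br onset.  Returns ``(trace,
    onset)``; ``onset`` is None when no ramp was injected (unobstructed
    trials, step-related cells, or a trigger that is never crossed).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t_start = trial.gap.time[0] if trial.gap is not None else -3500.0
    t = np.arange(np.floor(t_start), t_stop + 1.0)
    base = np.full_like(t, float(spec.baseline_rate))

    if spec.category == "STEP_RELATED":
        cycle = 2.0 * _step_period(trial)
        amp = spec.peak_rate - spec.baseline_rate
        rate = spec.baseline_rate + 0.5 * amp * (1.0 + np.cos(2.0 * np.pi * t / cycle))
        return RateTrace(time=t, rate=rate), None

    if trial.task == "unobstructed" or (trial.gap is None and spec.category != "NONE"):
        return RateTrace(time=t, rate=base), None

    if spec.category == "NONE":
        onset = -500.0 + rng.normal(0.0, 400.0)
    else:
        crossing = _trigger_crossing(spec, trial.gap)
        if crossing is None:
            return RateTrace(time=t, rate=base), None
        onset = crossing + rng.normal(0.0, spec.onset_jitter_sd)
    onset = min(onset, -1.0)  # truncate: the ramp always starts before the step

    baseline = spec.baseline_rate
    if trial.task == "visual_dissociation" and spec.tonic_vd_gain != 1.0:
        base = np.where(t < onset, baseline * spec.tonic_vd_gain, baseline)
        baseline_at_onset = baseline * spec.tonic_vd_gain
    else:
        baseline_at_onset = baseline

    rate = base.astype(float)
    ramp = (t >= onset) & (t <= spec.peak_time)
    frac = (t[ramp] - onset) / max(spec.peak_time - onset, 1.0)
    rate[ramp] = baseline_at_onset + (spec.peak_rate - baseline_at_onset) * frac
    after = t > spec.peak_time
    rate[after] = baseline + (spec.peak_rate - baseline) * np.exp(
        -(t[after] - spec.peak_time) / spec.decay_time
    )
    return RateTrace(time=t, rate=rate), float(onset)


def _step_period(trial: SyntheticTrial) -> float:
    onsets = trial.gait.br_onsets()
    if len(onsets) > 1:
        return float(np.median(np.diff(onsets)))
    return 500.0


# ---------------------------------------------------------------------------
# spike sampling


def sample_spikes(
    envelope: RateTrace,
    seed: int | np.random.Generator | None = None,
    refractory_ms: float = 1.0,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by thinning, with a refractory gap.

    Candidate events are drawn from a homogeneous process at the
    envelope maximum and kept with probability rate/max; accepted spikes
    closer than ``refractory_ms`` to their predecessor are dropped.
    """
    if np.any(envelope.rate < 0):
        raise ValueError("rate envelope must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rmax = float(np.max(envelope.rate)) if len(envelope.rate) else 0.0
    if rmax <= 0:
        return SpikeTrain(times=np.empty(0))
    t0, t1 = float(envelope.time[0]), float(envelope.time[-1])
    duration_s = (t1 - t0) / 1000.0
    n_cand = rng.poisson(rmax * duration_s)
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    keep = rng.uniform(0.0, 1.0, size=n_cand) < np.interp(cand, envelope.time, envelope.rate) / rmax
    cand = cand[keep]
    out: list[float] = []
    last = -np.inf
    for s in cand:
        if s - last >= refractory_ms:
            out.append(s)
            last = s
    return SpikeTrain(times=np.asarray(out))


# ---------------------------------------------------------------------------
# session generation


def _task_config(base: TaskConfig, task: str) -> TaskConfig:
    if task == "matched":
        return replace(base, obstacle_speed=base.treadmill_speed, acceleration=None)
    if task == "visual_dissociation":
        return replace(base, obstacle_speed=0.3, acceleration=None)
    if task.startswith("accel_"):
        cond = task.split("_")[1]
        accel = AccelerationProfile(trigger_condition=cond)
        return replace(base, obstacle_speed=accel.v_start, acceleration=accel)
    if task == "unobstructed":
        return replace(base, acceleration=None)
    raise ValueError(f"unknown task {task!r}")


def _trial_plan(design: SessionDesign) -> list[tuple[str, str]]:
    """(task, lead_limb) tuples for one cell's session."""
    plan: list[tuple[str, str]] = []
    for lead in ("left", "right"):
        plan += [("matched", lead)] * design.n_matched_per_lead
        plan += [("visual_dissociation", lead)] * design.n_vd_per_lead
    for cond in design.accel_conditions:
        # the condition letter names the lead sequence: 1L/2L are left-lead
        lead = "left" if cond.endswith("L") else "right"
        plan.extend([(f"accel_{cond}", lead)] * design.n_accel_per_condition)
    for i in range(design.n_unobstructed):
        plan.append(("unobstructed", "left" if i % 2 == 0 else "right"))
    return plan


def realize_trial(
    spec: CellSpec,
    task: str,
    lead: str,
    trial_seed: int,
    config: TaskConfig,
    initial_dtc: float = 200.0,
    gait_jitter_sd: float = 15.0,
    trial_id: str | None = None,
    gait: GaitTimeline | None = None,
) -> SyntheticTrial:
    """Build one trial deterministically from its per-trial seed.

    The seed is split into fixed sub-streams (gait, gap, envelope,
    spikes), so a trial stored with its seed and task label can be
    regenerated bit-for-bit -- including the gap trace, which session
    files therefore need not store sample-by-sample.
    """
    tcfg = _task_config(config, task)
    gait_rng, gap_rng, env_rng, spike_rng = np.random.default_rng(trial_seed).spawn(4)
    if gait is None:
        gait = gait_timeline(
            tcfg, n_steps=12, jitter_sd=gait_jitter_sd, lead_limb=lead, seed=gait_rng
        )
    gap = None
    if task != "unobstructed":
        gap = gap_trace(tcfg, gait, initial_dtc=initial_dtc, seed=gap_rng)
    trial = SyntheticTrial(
        trial_id=trial_id or f"{spec.cell_id}-{task}-{lead}-{trial_seed}",
        cell_id=spec.cell_id,
        task=task,  # type: ignore[arg-type]
        lead_limb=lead,
        gait=gait,
        spikes=SpikeTrain(times=np.empty(0)),
        gap=gap,
        trial_seed=trial_seed,
        initial_dtc=initial_dtc,
    )
    env, truth = rate_envelope(spec, trial, seed=env_rng)
    trial.spikes = sample_spikes(env, seed=spike_rng)
    trial.truth_onset = truth
    return trial


def generate_session(
    specs: Iterable[CellSpec],
    design: SessionDesign | None = None,
    config: TaskConfig | None = None,
    seed: int | None = None,
    initial_dtc: float = 200.0,
    gait_jitter_sd: float = 15.0,
) -> Session:
    """Generate a full labelled session for a set of cells.

    For every cell the trial plan of ``design`` is realized: gait
    timeline, gap trace (where an obstacle is present), rate envelope
    with the cell's trigger logic, and Poisson spikes.  All randomness
    flows from ``seed``.  A design that violates the inclusion criteria
    is generated anyway but the session is flagged.
    """
    design = design or SessionDesign()
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    ok = design.meets_inclusion()
    if not ok:
        warnings.warn("session design violates the inclusion criteria", stacklevel=2)

    plan = _trial_plan(design)
    trials: dict[str, list[SyntheticTrial]] = {}
    for spec in specs:
        cell_trials: list[SyntheticTrial] = []
        for k, (task, lead) in enumerate(plan):
            trial_seed = int(rng.integers(2**31))
            cell_trials.append(
                realize_trial(
                    spec,
                    task,
                    lead,
                    trial_seed,
                    config=config,
                    initial_dtc=initial_dtc,
                    gait_jitter_sd=gait_jitter_sd,
                    trial_id=f"{spec.cell_id}-{k:03d}-{task}-{lead[0].upper()}",
                )
            )
        trials[spec.cell_id] = cell_trials
    return Session(
        cells=list(specs),
        trials=trials,
        design=design,
        base_config=config,
        seed=seed,
        meets_inclusion=ok,
    )


def make_population(
    n_dtc: int = 40,
    n_ttc: int = 40,
    n_none: int = 20,
    n_step_related: int = 0,
    onset_jitter_sd: float = 150.0,
    seed: int | None = None,
    **spec_kwargs,
) -> list[CellSpec]:
    """Draw a labelled cell population with field-typical trigger ranges.

    DTC triggers are uniform on 20-40 cm and TTC triggers uniform on
    300-1000 ms, the ranges over which recorded cells began to
    discharge.
    """
    rng = np.random.default_rng(seed)
    specs: list[CellSpec] = []
    for i in range(n_dtc):
        specs.append(
            CellSpec(
                cell_id=f"dtc{i:03d}",
                category="DTC",
                trigger_dtc_cm=float(rng.uniform(20.0, 40.0)),
                trigger_ttc_ms=None,
                onset_jitter_sd=onset_jitter_sd,
                **spec_kwargs,
            )
        )
    for i in range(n_ttc):
        specs.append(
            CellSpec(
                cell_id=f"ttc{i:03d}",
                category="TTC",
                trigger_dtc_cm=None,
                trigger_ttc_ms=float(rng.uniform(300.0, 1000.0)),
                onset_jitter_sd=onset_jitter_sd,
                **spec_kwargs,
            )
        )
    for i in range(n_none):
        specs.append(
            CellSpec(
                cell_id=f"none{i:03d}",
                category="NONE",
                trigger_dtc_cm=None,
                trigger_ttc_ms=None,
                onset_jitter_sd=onset_jitter_sd,
                **spec_kwargs,
            )
        )
    for i in range(n_step_related):
        specs.append(
            CellSpec(
                cell_id=f"step{i:03d}",
                category="STEP_RELATED",
                trigger_dtc_cm=None,
                trigger_ttc_ms=None,
                onset_jitter_sd=onset_jitter_sd,
                **spec_kwargs,
            )
        )
    return specs
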