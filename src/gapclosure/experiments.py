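"""Canned simulation studies used for validation and benchmarking.

Each function realizes one study at its documented conditions --
generating synthetic cells one at a time (sessions are discarded after
analysis, keeping memory flat), running the standard pipeline, and
returning summary numbers.  They are the single source of truth for the
package's headline checks: the modulation-index landmarks for ideal
cells, ground-truth category recovery, single-trial onset accuracy, the
population ramp ordering across tasks, and the acceleration-induced
slope increase.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from typing import Sequence

import numpy as np

from gapclosure import cell_classification as cls
from gapclosure import population_analysis as pop
from gapclosure.synthetic_cells import (
    CellSpec,
    SessionDesign,
    generate_session,
    make_population,
)

@contextmanager
def _quiet():
    """Suppress inclusion warnings for deliberately partial study designs."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="session design violates the inclusion criteria"
        )
        yield


__all__ = [
    "index_landmarks",
    "category_recovery",
    "onset_accuracy",
    "population_ramp_onsets",
    "acceleration_slope_ratio",
]


def _analyze_population(
    specs: Sequence[CellSpec],
    design: SessionDesign,
    seed: int,
    config: cls.AnalysisConfig,
) -> list[tuple[CellSpec, cls.CellClassification]]:
    """Generate and classify cells one at a time (memory stays flat)."""
    rng = np.random.default_rng(seed)
    out = []
    for spec in specs:
        with _quiet():
            session = generate_session([spec], design, seed=int(rng.integers(2**31)))
        out.append(
            (spec, cls.analyze_cell(spec.cell_id, session.trials[spec.cell_id], config))
        )
    return out


def index_landmarks(
    n_cells: int = 100,
    onset_jitter_sd: float = 50.0,
    n_trials_per_group: int = 20,
    seed: int = 0,
    config: cls.AnalysisConfig | None = None,
) -> dict[str, float]:
    """Mean modulation indices of ideal distance- and time-tuned cells.

    Simulates ``n_cells`` DTC-tuned and ``n_cells`` TTC-tuned cells
    (triggers uniform over their field-typical ranges, small onset
    jitter, ``n_trials_per_group`` trials per task x lead condition) and
    returns the population-mean index on each axis.  Ideal DTC cells
    should land near (index_dtc, index_ttc) = (0, 1) and ideal TTC cells
    near (-1, 0).
    """
    config = config or cls.AnalysisConfig()
    rng = np.random.default_rng(seed)
    specs = make_population(
        n_dtc=n_cells, n_ttc=n_cells, n_none=0,
        onset_jitter_sd=onset_jitter_sd, seed=int(rng.integers(2**31)),
    )
    design = SessionDesign(
        n_matched_per_lead=n_trials_per_group,
        n_vd_per_lead=n_trials_per_group,
        accel_conditions=(),
        n_unobstructed=5,
    )
    results = _analyze_population(specs, design, int(rng.integers(2**31)), config)
    by_cat = {"DTC": [], "TTC": []}
    for spec, c in results:
        by_cat[spec.category].append((c.index_dtc, c.index_ttc))
    d = np.asarray(by_cat["DTC"])
    t = np.asarray(by_cat["TTC"])
    return {
        "dtc_cells_index_dtc": float(d[:, 0].mean()),
        "dtc_cells_index_ttc": float(d[:, 1].mean()),
        "ttc_cells_index_dtc": float(t[:, 0].mean()),
        "ttc_cells_index_ttc": float(t[:, 1].mean()),
        "n_cells_per_category": int(n_cells),
    }


def category_recovery(
    n_dtc: int = 40,
    n_ttc: int = 40,
    n_none: int = 20,
    onset_jitter_sd: float = 150.0,
    n_trials_per_group: int = 20,
    seed: int = 0,
    config: cls.AnalysisConfig | None = None,
) -> dict[str, float]:
    """Ground-truth category recovery of the full pipeline.

    Labelled cells are simulated at the stated jitter with
    inclusion-satisfying trial counts, classified blind to their labels,
    and scored.  Returns the recovery fraction and the DTC<->TTC swap
    fraction alongside the confusion counts.
    """
    config = config or cls.AnalysisConfig()
    rng = np.random.default_rng(seed)
    specs = make_population(
        n_dtc=n_dtc, n_ttc=n_ttc, n_none=n_none,
        onset_jitter_sd=onset_jitter_sd, seed=int(rng.integers(2**31)),
    )
    design = SessionDesign(
        n_matched_per_lead=n_trials_per_group,
        n_vd_per_lead=n_trials_per_group,
        accel_conditions=("1L", "2L", "1R", "2R"),
        n_accel_per_condition=3,
        n_unobstructed=5,
    )
    results = _analyze_population(specs, design, int(rng.integers(2**31)), config)
    n = len(results)
    correct = sum(1 for spec, c in results if c.category == spec.category)
    swaps = sum(
        1 for spec, c in results if {spec.category, c.category} == {"DTC", "TTC"}
    )
    confusion: dict[str, int] = {}
    for spec, c in results:
        key = f"{spec.category}->{c.category}"
        confusion[key] = confusion.get(key, 0) + 1
    return {
        "n_cells": n,
        "recovery_fraction": correct / n,
        "dtc_ttc_swap_fraction": swaps / n,
        "confusion": confusion,
    }


def onset_accuracy(
    n_trials: int = 500,
    trigger_dtc_cm: float = 30.0,
    onset_jitter_sd: float = 0.0,
    baseline_rate: float = 10.0,
    peak_rate: float = 60.0,
    seed: int = 0,
    config: cls.AnalysisConfig | None = None,
    batch: int = 50,
) -> dict[str, float]:
    """Median absolute error of detected vs injected onsets.

    ``n_trials`` matched-task trials of one distance-tuned cell are
    generated in batches (each batch is one detection group, mimicking
    a recording block), detection is run, and detected onsets are
    compared with the injected ground truth.
    """
    config = config or cls.AnalysisConfig()
    rng = np.random.default_rng(seed)
    spec = CellSpec(
        cell_id="probe", category="DTC", trigger_dtc_cm=trigger_dtc_cm,
        onset_jitter_sd=onset_jitter_sd,
        baseline_rate=baseline_rate, peak_rate=peak_rate,
    )
    errors: list[float] = []
    detected = 0
    remaining = n_trials
    while remaining > 0:
        k = min(batch, remaining)
        remaining -= k
        design = SessionDesign(
            n_matched_per_lead=k, n_vd_per_lead=0, accel_conditions=(), n_unobstructed=0
        )
        with _quiet():
            session = generate_session([spec], design, seed=int(rng.integers(2**31)))
        trials = [
            t for t in session.trials["probe"]
            if t.task == "matched" and t.lead_limb == "left"
        ]
        for t, refined, _cand in cls.detect_group_onsets(trials, config):
            errors.append(refined - t.truth_onset)
            detected += 1
    errors_arr = np.asarray(errors)
    return {
        "n_trials": n_trials,
        "n_detected": detected,
        "median_abs_error_ms": float(np.median(np.abs(errors_arr))),
        "median_error_ms": float(np.median(errors_arr)),
    }


def _population_trace(
    specs: Sequence[CellSpec],
    task: str,
    n_trials: int,
    seed: int,
) -> pop.PopulationTrace:
    rng = np.random.default_rng(seed)
    kwargs = {
        "n_matched_per_lead": n_trials if task == "matched" else 0,
        "n_vd_per_lead": n_trials if task == "visual_dissociation" else 0,
        "accel_conditions": (),
        "n_unobstructed": 0,
    }
    if task.startswith("accel_"):
        kwargs = {
            "n_matched_per_lead": 0,
            "n_vd_per_lead": 0,
            "accel_conditions": (task.split("_")[1],),
            "n_accel_per_condition": n_trials,
            "n_unobstructed": 0,
        }
    design = SessionDesign(**kwargs)
    pehs = []
    for spec in specs:
        with _quiet():
            session = generate_session([spec], design, seed=int(rng.integers(2**31)))
        trains = [t.spikes for t in session.trials_for(spec.cell_id, task)]
        pehs.append(pop.build_peh(trains))
    return pop.population_average(pehs)


def population_ramp_onsets(
    n_cells: int = 12,
    n_trials: int = 10,
    onset_jitter_sd: float = 50.0,
    seed: int = 0,
) -> dict[str, float]:
    """Population ramp onsets per task for DTC- and TTC-tuned groups.

    Distance-tuned populations should ramp up earlier (relative to the
    step) in the visual dissociation task than in the matched task;
    time-tuned populations should superimpose.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for cat in ("DTC", "TTC"):
        specs = make_population(
            n_dtc=n_cells if cat == "DTC" else 0,
            n_ttc=n_cells if cat == "TTC" else 0,
            n_none=0,
            onset_jitter_sd=onset_jitter_sd,
            seed=int(rng.integers(2**31)),
        )
        for task in ("matched", "visual_dissociation"):
            trace = _population_trace(specs, task, n_trials, int(rng.integers(2**31)))
            out[f"{cat}_{task}_onset_ms"] = pop.population_onset(trace)
            out[f"{cat}_{task}_peak_ms"] = float(
                trace.time[np.argmax(trace.rate)]
            )
    return out


def acceleration_slope_ratio(
    n_cells: int = 12,
    n_trials: int = 10,
    onset_jitter_sd: float = 50.0,
    seed: int = 0,
) -> dict[str, float]:
    """Onset-to-peak slope of a DTC population: 1L acceleration vs unperturbed.

    The late acceleration delays the trigger crossing while the peak
    stays locked to the step, so the population ramp must steepen; the
    ratio of the two slopes is returned.
    """
    rng = np.random.default_rng(seed)
    specs = make_population(
        n_dtc=n_cells, n_ttc=0, n_none=0,
        onset_jitter_sd=onset_jitter_sd, seed=int(rng.integers(2**31)),
    )
    out: dict[str, float] = {}
    for task in ("visual_dissociation", "accel_1L"):
        trace = _population_trace(specs, task, n_trials, int(rng.integers(2**31)))
        onset = pop.population_onset(trace)
        out[f"{task}_onset_ms"] = onset
        out[f"{task}_slope"] = pop.ramp_slope(trace, onset)
    out["slope_ratio"] = out["accel_1L_slope"] / out["visual_dissociation_slope"]
    return out
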