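"""Session files, reports, and the end-to-end pipeline.

A session is stored as a single JSON document: task configuration, cell
specs (with their ground-truth block), and per-trial event tables with
spike times in ms.  Gap traces are not stored sample-by-sample -- each
trial carries the child seed it was generated from, and the trace is
regenerated exactly on read.  Real recordings, should they ever exist,
would enter through the same schema with the truth block omitted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from gapclosure import cell_classification as cls
from gapclosure import population_analysis as pop
from gapclosure.synthetic_cells import (
    CellSpec,
    Session,
    SessionDesign,
    SpikeTrain,
    SyntheticTrial,
    _task_config,
    generate_session,
    make_population,
)
from gapclosure.task_kinematics import (
    AccelerationProfile,
    DriftModel,
    GaitTimeline,
    TaskConfig,
    gap_trace,
)

__all__ = [
    "SCHEMA_VERSION",
    "write_session",
    "read_session",
    "classification_report",
    "run_pipeline",
]

SCHEMA_VERSION = 1
logger = logging.getLogger("gapclosure")


# ---------------------------------------------------------------------------
# serialization helpers


def _config_to_dict(config: TaskConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _config_from_dict(d: dict) -> TaskConfig:
    d = dict(d)
    if d.get("acceleration"):
        d["acceleration"] = AccelerationProfile(**d["acceleration"])
    else:
        d["acceleration"] = None
    if d.get("drift"):
        d["drift"] = DriftModel(**d["drift"])
    else:
        d["drift"] = None
    return TaskConfig(**d)


def _trial_to_dict(trial: SyntheticTrial) -> dict:
    return {
        "trial_id": trial.trial_id,
        "cell_id": trial.cell_id,
        "task": trial.task,
        "lead_limb": trial.lead_limb,
        "trial_seed": trial.trial_seed,
        "initial_dtc": trial.initial_dtc,
        "gait_events": [[t, limb, kind] for t, limb, kind in trial.gait.events],
        "lead_limb_gait": trial.gait.lead_limb,
        "spike_times_ms": [round(float(t), 4) for t in trial.spikes.times],
        "truth_onset_ms": trial.truth_onset,
    }


def _trial_from_dict(d: dict, base_config: TaskConfig) -> SyntheticTrial:
    required = ("trial_id", "cell_id", "task", "lead_limb", "spike_times_ms", "gait_events")
    for key in required:
        if key not in d:
            raise ValueError(
                f"session schema violation: trial {d.get('trial_id', '<unknown>')} "
                f"is missing field {key!r}"
            )
    gait = GaitTimeline(
        events=[(float(t), limb, kind) for t, limb, kind in d["gait_events"]],
        lead_limb=d.get("lead_limb_gait", d["lead_limb"]),
    )
    gap = None
    if d["task"] != "unobstructed":
        tcfg = _task_config(base_config, d["task"])
        if d.get("trial_seed") is None:
            raise ValueError(
                f"trial {d['trial_id']}: cannot regenerate gap trace without trial_seed"
            )
        gap_rng = np.random.default_rng(int(d["trial_seed"])).spawn(4)[1]
        gap = gap_trace(
            tcfg, gait, initial_dtc=float(d.get("initial_dtc") or 200.0), seed=gap_rng
        )
    return SyntheticTrial(
        trial_id=d["trial_id"],
        cell_id=d["cell_id"],
        task=d["task"],
        lead_limb=d["lead_limb"],
        gait=gait,
        spikes=SpikeTrain(times=np.asarray(d["spike_times_ms"], dtype=float)),
        gap=gap,
        truth_onset=d.get("truth_onset_ms"),
        trial_seed=d.get("trial_seed"),
        initial_dtc=d.get("initial_dtc"),
    )


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to a JSON file (deterministic field order)."""
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": session.seed,
        "meets_inclusion": session.meets_inclusion,
        "design": dataclasses.asdict(session.design),
        "base_config": _config_to_dict(session.base_config),
        "cells": [dataclasses.asdict(c) for c in session.cells],
        "trials": {
            cid: [_trial_to_dict(t) for t in ts] for cid, ts in session.trials.items()
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_session(path: str | Path) -> Session:
    """Read a session file; schema violations name the offending trial."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported session schema version {doc.get('schema_version')}")
    base_config = _config_from_dict(doc["base_config"])
    design = SessionDesign(**{**doc["design"], "accel_conditions": tuple(doc["design"]["accel_conditions"])})
    cells = [CellSpec(**c) for c in doc["cells"]]
    trials = {
        cid: [_trial_from_dict(t, base_config) for t in ts]
        for cid, ts in doc["trials"].items()
    }
    return Session(
        cells=cells,
        trials=trials,
        design=design,
        base_config=base_config,
        seed=doc.get("seed"),
        meets_inclusion=bool(doc.get("meets_inclusion", True)),
    )


# ---------------------------------------------------------------------------
# reports


def detection_report(
    session: Session, config: cls.AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-trial onset detections for every cell: trial_id, onset, DTC/TTC."""
    config = config or cls.AnalysisConfig()
    rows = []
    for spec in session.cells:
        trials = session.trials[spec.cell_id]
        for task in ("matched", "visual_dissociation"):
            group = [t for t in trials if t.task == task]
            if not group:
                continue
            for t, refined, cand in cls.detect_group_onsets(group, config):
                dtc, ttc = cls.od.map_onset_to_gap(cand, t.gap)
                rows.append(
                    {
                        "cell_id": spec.cell_id,
                        "trial_id": t.trial_id,
                        "task": task,
                        "lead_limb": t.lead_limb,
                        "onset_ms": cand,
                        "onset_refined_ms": refined,
                        "dtc_cm": dtc,
                        "ttc_ms": ttc,
                        "truth_onset_ms": t.truth_onset,
                    }
                )
    return pd.DataFrame(rows)


def classification_report(
    session: Session,
    config: cls.AnalysisConfig | None = None,
    seed: int | None = None,
    with_bootstrap: bool = False,
) -> pd.DataFrame:
    """Classify every cell in a session; one row per cell.

    Cells in sessions that violate the inclusion criteria are marked
    excluded and not analysed.
    """
    config = config or cls.AnalysisConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for spec in session.cells:
        if not session.meets_inclusion:
            rows.append(
                {
                    "cell_id": spec.cell_id,
                    "true_category": spec.category,
                    "category": "EXCLUDED",
                    "included": False,
                    "reason": "session below inclusion criteria",
                }
            )
            continue
        c = cls.analyze_cell(
            spec.cell_id,
            session.trials[spec.cell_id],
            config=config,
            seed=rng,
            with_bootstrap=with_bootstrap,
        )
        rows.append(
            {
                "cell_id": c.cell_id,
                "true_category": spec.category,
                "category": c.category,
                "p_dtc": c.p_dtc,
                "p_ttc": c.p_ttc,
                "index_dtc": c.index_dtc,
                "index_ttc": c.index_ttc,
                "ci_dtc_lo": c.ci_dtc[0] if c.ci_dtc else np.nan,
                "ci_dtc_hi": c.ci_dtc[1] if c.ci_dtc else np.nan,
                "ci_ttc_lo": c.ci_ttc[0] if c.ci_ttc else np.nan,
                "ci_ttc_hi": c.ci_ttc[1] if c.ci_ttc else np.nan,
                "step_advanced": c.step_advanced,
                "limb_independent": c.limb_independent,
                "n_onsets": c.n_onsets,
                "outlier_fraction": c.outlier_fraction,
                "included": c.included,
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows)


def category_summary(report: pd.DataFrame) -> dict[str, Any]:
    counts = report["category"].value_counts().to_dict()
    out: dict[str, Any] = {"n_cells": int(len(report)), "counts": counts}
    if "true_category" in report:
        ok = (report["category"] == report["true_category"]).mean()
        out["recovery_fraction"] = float(ok)
    return out


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "results",
    seed: int = 0,
    stages: tuple[str, ...] = ("simulate", "classify", "population", "limbmodel"),
) -> dict[str, Any]:
    """Simulate a session and run every analysis stage.

    ``config`` is a flat dictionary (typically loaded from YAML/JSON)
    with optional ``task`` (TaskConfig fields: speeds in m/s,
    step_period, drift/acceleration blocks), ``simulate``, ``analysis``
    and ``limbmodel`` sections; anything omitted uses the documented
    defaults.  All randomness derives from ``seed``.  Returns a summary
    dictionary; per-stage tables are written under ``out_dir``.
    """
    from gapclosure import limb_selection as lm

    config = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": seed, "stages": {}}
    rng = np.random.default_rng(seed)

    sim = dict(config.get("simulate", {}))
    session: Session | None = None
    if "simulate" in stages:
        t0 = time.perf_counter()
        specs = make_population(
            n_dtc=sim.get("n_dtc", 10),
            n_ttc=sim.get("n_ttc", 10),
            n_none=sim.get("n_none", 5),
            n_step_related=sim.get("n_step_related", 0),
            onset_jitter_sd=sim.get("onset_jitter_sd", 150.0),
            seed=int(rng.integers(2**31)),
        )
        design = SessionDesign(
            **{
                k: sim[k]
                for k in (
                    "n_matched_per_lead",
                    "n_vd_per_lead",
                    "n_accel_per_condition",
                    "n_unobstructed",
                )
                if k in sim
            }
        )
        task_cfg = _config_from_dict(
            {**_config_to_dict(TaskConfig()), **config.get("task", {})}
        )
        session = generate_session(
            specs, design, config=task_cfg, seed=int(rng.integers(2**31))
        )
        write_session(session, out / "session.json")
        summary["stages"]["simulate"] = {
            "n_cells": len(specs),
            "n_trials": sum(len(v) for v in session.trials.values()),
            "seconds": round(time.perf_counter() - t0, 2),
        }
        logger.info("simulate: %s", summary["stages"]["simulate"])

    if "classify" in stages:
        if session is None:
            session = read_session(out / "session.json")
        t0 = time.perf_counter()
        acfg = cls.AnalysisConfig(**config.get("analysis", {}))
        report = classification_report(
            session, acfg, seed=int(rng.integers(2**31))
        )
        report.to_csv(out / "classification.csv", index=False)
        summary["stages"]["classify"] = {
            **category_summary(report),
            "seconds": round(time.perf_counter() - t0, 2),
        }
        logger.info("classify: %s", summary["stages"]["classify"])

    if "population" in stages and session is not None:
        t0 = time.perf_counter()
        rows = []
        for task in ("matched", "visual_dissociation"):
            for cat in ("DTC", "TTC"):
                cells = [s for s in session.cells if s.category == cat]
                if len(cells) < 2:
                    continue
                pehs = [
                    pop.build_peh(
                        [t.spikes for t in session.trials_for(s.cell_id, task)]
                    )
                    for s in cells
                ]
                trace = pop.population_average(pehs)
                onset = pop.population_onset(trace)
                slope = pop.ramp_slope(trace, onset)
                rows.append(
                    {"task": task, "category": cat, "n_cells": trace.n_cells,
                     "onset_ms": onset, "slope_per_s2": slope}
                )
        pd.DataFrame(rows).to_csv(out / "population.csv", index=False)
        summary["stages"]["population"] = {
            "rows": rows,
            "seconds": round(time.perf_counter() - t0, 2),
        }
        logger.info("population: %s", summary["stages"]["population"])

    if "limbmodel" in stages:
        t0 = time.perf_counter()
        lcfg = lm.LimbModelConfig(**config.get("limbmodel", {}))
        res = lm.acceleration_reversal_experiment(lcfg)
        sweep = lm.phase_sweep(lcfg)
        pd.DataFrame(sweep).to_csv(out / "limbmodel_sweep.csv", index=False)
        summary["stages"]["limbmodel"] = {
            **res,
            "seconds": round(time.perf_counter() - t0, 2),
        }
        logger.info("limbmodel: %s", summary["stages"]["limbmodel"])

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
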