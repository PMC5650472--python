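"""Statistical classification of cells as DTC- or TTC-related.

The logic mirrors the dual-ANOVA design of the source experiments: for
every trial the onset of the discharge change is located and the
distance-to-contact (DTC) and time-to-contact (TTC) at that moment are
read off the gap trace.  A cell whose onset tracks a fixed *distance*
shows constant DTC-at-onset across the matched and visual dissociation
tasks but task-dependent TTC-at-onset, and vice versa.  Two one-way
ANOVAs (alpha = 0.01) across the four task x lead-limb groups test each
variable; the category follows from which variable is constant.

A per-cell modulation index summarizes the same dissociation on the
rate profiles directly: trial-averaged rates are re-expressed as
functions of DTC and of TTC, Z-scored pointwise across the four
task x lead profiles, and the visual-dissociation-minus-matched
contrast is averaged over the grid.  Ideal distance-tuned cells land
near (index_dtc, index_ttc) = (0, 1) and ideal time-tuned cells near
(-1, 0).  A within-condition bootstrap over trials yields percentile
confidence intervals for the indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from gapclosure import onset_detection as od
from gapclosure.task_kinematics import GapTrace

__all__ = [
    "AnalysisConfig",
    "OnsetSample",
    "CellClassification",
    "remove_outliers",
    "anova_onset",
    "classify_cell",
    "posthoc_tests",
    "rate_profile_on_grid",
    "modulation_index",
    "bootstrap_index",
    "flag_step_advanced_and_limb_independent",
    "trial_onset_sample",
    "analyze_cell",
]

GROUPS = (
    ("matched", "left"),
    ("matched", "right"),
    ("visual_dissociation", "left"),
    ("visual_dissociation", "right"),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and grids of the classification pipeline."""

    alpha_anova: float = 0.01
    alpha_t: float = 0.05  # Bonferroni-corrected across the six pairwise tests
    outlier_k: float = 1.5  # Tukey fence multiplier on the IQR
    advance_threshold: float = 200.0  # ms; step-advanced if onset earlier
    limb_indep_threshold: float = 200.0  # ms; max end-of-discharge difference
    n_bootstrap: int = 1000
    dtc_grid_max: float = 45.0  # cm
    dtc_grid_step: float = 1.0
    ttc_grid_max: float = 1500.0  # ms
    ttc_grid_step: float = 10.0
    sustain: float = 50.0  # ms, onset debounce
    refine_cutoff_hz: float = 1.5  # smoothing for single-trial onset localization
    refine_window_ms: float = 800.0  # tail clip around the group onset
    refine_noise_sd_ms: float = 250.0  # localization noise assumed by the shrinkage
    onset_prior_sd_ms: float = 0.0  # optional weak MAP prior on single-trial onsets (0 = off)
    profile_smooth_dtc_cm: float = 2.25  # Gaussian SD along the DTC grid
    profile_smooth_ttc_ms: float = 50.0  # Gaussian SD along the TTC grid

    def __post_init__(self) -> None:
        if not (0 < self.alpha_anova < 1 and 0 < self.alpha_t < 1):
            raise ValueError("alphas must lie in (0, 1)")
        for name in ("outlier_k", "advance_threshold", "limb_indep_threshold", "n_bootstrap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def dtc_grid(self) -> np.ndarray:
        return np.arange(0.0, self.dtc_grid_max + 1e-9, self.dtc_grid_step)

    @property
    def ttc_grid(self) -> np.ndarray:
        return np.arange(0.0, self.ttc_grid_max + 1e-9, self.ttc_grid_step)


@dataclass(frozen=True)
class OnsetSample:
    """Per-trial discharge onset with the gap variables at that moment."""

    trial_id: str
    task: str
    lead_condition: str  # 'left' | 'right'
    onset: float  # ms, < 0
    dtc: float  # cm
    ttc: float  # ms


@dataclass
class CellClassification:
    """Classification record for one cell."""

    cell_id: str
    category: str  # 'DTC' | 'TTC' | 'BOTH' | 'NONE'
    p_dtc: float
    p_ttc: float
    index_dtc: float
    index_ttc: float
    posthoc_dtc: list[dict] = field(default_factory=list)
    posthoc_ttc: list[dict] = field(default_factory=list)
    ci_dtc: tuple[float, float] | None = None
    ci_ttc: tuple[float, float] | None = None
    step_advanced: bool | None = None
    limb_independent: bool | None = None
    included: bool = True
    reason: str = ""
    n_onsets: int = 0
    outlier_fraction: float = 0.0


# ---------------------------------------------------------------------------
# elementary statistics


def remove_outliers(values: Sequence[float], k: float = 1.5) -> tuple[np.ndarray, float, bool]:
    """Drop values outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation.  Returns ``(kept, removed_fraction,
    applied)``; fewer than four values pass through untouched with
    ``applied = False``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        return v, 0.0, False
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - k * iqr) & (v <= q3 + k * iqr)
    return v[keep], float(1.0 - keep.mean()), True


def anova_onset(groups: Mapping[tuple[str, str], Sequence[float]]) -> float:
    """One-way fixed-effects ANOVA p-value across the task x lead groups.

    ``groups`` maps (task, lead) to the per-trial DTC- or TTC-at-onset
    values.  Identical values in every group give F = 0 behaviour
    (p = 1).  An empty group raises, naming the group.
    """
    arrays = []
    for key in groups:
        a = np.asarray(groups[key], dtype=float)
        if len(a) == 0:
            raise ValueError(f"empty ANOVA group {key}")
        arrays.append(a)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 1.0
    with np.errstate(invalid="ignore"):
        res = sps.f_oneway(*arrays)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def classify_cell(p_dtc: float, p_ttc: float, config: AnalysisConfig = AnalysisConfig()) -> str:
    """Category from the two ANOVA p-values.

    A cell related to *distance* keeps DTC-at-onset constant across
    tasks (non-significant DTC ANOVA) while its TTC-at-onset shifts
    (significant TTC ANOVA); symmetrically for time-related cells.
    """
    a = config.alpha_anova
    sig_dtc, sig_ttc = p_dtc < a, p_ttc < a
    if sig_ttc and not sig_dtc:
        return "DTC"
    if sig_dtc and not sig_ttc:
        return "TTC"
    if sig_dtc and sig_ttc:
        return "BOTH"
    return "NONE"


def posthoc_tests(
    groups: Mapping[tuple[str, str], Sequence[float]],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[dict]:
    """All six pairwise t-tests with Bonferroni correction.

    Each entry carries the pair, raw and adjusted p, significance at
    ``alpha_t``, and whether the pair contrasts tasks, lead conditions,
    or both.  Pairs with zero pooled variance are flagged degenerate.
    """
    keys = list(groups)
    n_pairs = len(keys) * (len(keys) - 1) // 2
    out: list[dict] = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a = np.asarray(groups[keys[i]], dtype=float)
            b = np.asarray(groups[keys[j]], dtype=float)
            degenerate = np.ptp(np.concatenate([a, b])) == 0
            if degenerate:
                p_raw = 1.0
            else:
                p_raw = float(sps.ttest_ind(a, b).pvalue)
                if np.isnan(p_raw):
                    p_raw, degenerate = 1.0, True
            p_adj = min(1.0, p_raw * n_pairs)
            out.append(
                {
                    "pair": (keys[i], keys[j]),
                    "task_contrast": keys[i][0] != keys[j][0],
                    "lead_contrast": keys[i][1] != keys[j][1],
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "significant": p_adj < config.alpha_t,
                    "degenerate": degenerate,
                }
            )
    return out


# ---------------------------------------------------------------------------
# modulation index


def rate_profile_on_grid(
    rate: od.RateTrace,
    gap: GapTrace,
    grid: np.ndarray,
    axis: str,
    smooth_sd: float = 0.0,
) -> np.ndarray:
    """Rate as a function of DTC or TTC on ``grid`` for one trial.

    The gap variable decreases monotonically toward contact, so each
    grid value maps to the (last) time it was crossed; the filtered rate
    is interpolated there.  ``smooth_sd`` (in grid units) applies a
    Gaussian smoothing along the grid, reducing the point noise that
    otherwise dilutes the standardized task contrast.  Grid values never
    reached within the trace are NaN.
    """
    x = gap.dtc if axis == "dtc" else gap.ttc
    # reverse so xp is increasing for np.interp
    t_of_x = np.interp(grid, x[::-1], gap.time[::-1])
    prof = np.interp(t_of_x, rate.time, rate.rate)
    if smooth_sd > 0:
        step = float(grid[1] - grid[0]) if len(grid) > 1 else 1.0
        prof = ndimage.gaussian_filter1d(prof, smooth_sd / step, mode="nearest")
    prof = np.where(grid > x.max(), np.nan, prof)
    return prof


def modulation_index(
    profiles: Mapping[tuple[str, str], np.ndarray],
) -> float:
    """VD-minus-matched contrast of pointwise-standardized rate profiles.

    ``profiles`` maps the four (task, lead) pairs to trial-averaged rate
    profiles on a common DTC or TTC grid.  At every grid point the four
    profile values are Z-scored (sample SD); the index is the grid
    average of ``mean(Z_vd) - mean(Z_matched)``.  Identical profiles give
    0; a cell active earlier (in grid units) during visual dissociation
    gives a positive index.
    """
    for key in GROUPS:
        if key not in profiles:
            raise ValueError(f"missing profile for group {key}")
    P = np.vstack([np.asarray(profiles[key], dtype=float) for key in GROUPS])
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(P, axis=0)
        sd = np.nanstd(P, axis=0, ddof=1)
        Z = (P - mu) / np.where(sd < 1e-12, np.nan, sd)
        contrast = (Z[2] + Z[3]) / 2.0 - (Z[0] + Z[1]) / 2.0
        if np.all(np.isnan(contrast)):
            return 0.0
        return float(np.nanmean(contrast))


def _group_profiles(
    per_trial: Mapping[tuple[str, str], np.ndarray],
) -> dict[tuple[str, str], np.ndarray]:
    with np.errstate(invalid="ignore"):
        return {k: np.nanmean(v, axis=0) for k, v in per_trial.items()}


def bootstrap_index(
    per_trial_profiles: Mapping[tuple[str, str], np.ndarray],
    config: AnalysisConfig = AnalysisConfig(),
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile 95% CI of the modulation index by trial resampling.

    ``per_trial_profiles`` maps each (task, lead) group to an
    (n_trials x grid) array of single-trial rate profiles.  Trials are
    resampled with replacement within each group and the index
    recomputed ``n_bootstrap`` times.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    reps = np.empty(config.n_bootstrap)
    mats = {k: np.asarray(v, dtype=float) for k, v in per_trial_profiles.items()}
    for b in range(config.n_bootstrap):
        prof = {}
        for k, m in mats.items():
            idx = rng.integers(0, len(m), size=len(m))
            with np.errstate(invalid="ignore"):
                prof[k] = np.nanmean(m[idx], axis=0)
        reps[b] = modulation_index(prof)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# step-advanced / limb-independent flags


def flag_step_advanced_and_limb_independent(
    onset_by_lead: Mapping[str, float | None],
    offset_by_lead: Mapping[str, float | None],
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[bool, bool]:
    """Flags from the lead-condition averaged traces.

    ``step_advanced``: the averaged discharge change begins more than
    ``advance_threshold`` ms before the lead-limb Br onset in both lead
    conditions.  ``limb_independent``: the end of discharge (each
    relative to its own lead limb's Br onset) differs by less than
    ``limb_indep_threshold`` ms between lead conditions.
    """
    onsets = [onset_by_lead.get("left"), onset_by_lead.get("right")]
    step_advanced = all(o is not None and o < -config.advance_threshold for o in onsets)
    off_l, off_r = offset_by_lead.get("left"), offset_by_lead.get("right")
    limb_independent = (
        off_l is not None
        and off_r is not None
        and abs(off_l - off_r) < config.limb_indep_threshold
    )
    return step_advanced, limb_independent


# ---------------------------------------------------------------------------
# per-cell driver

AVG_GRID = np.arange(-3500.0, 2000.0 + 1.0)


def _smooth_trace(trial) -> od.RateTrace:
    grid = od.detection_grid(trial.gap)
    return od.lowpass(od.instantaneous_frequency(trial.spikes, grid))


def group_average_trace(smooths: Sequence[od.RateTrace], grid: np.ndarray = AVG_GRID) -> od.RateTrace:
    """Across-trial average rate on a common grid."""
    rates = [np.interp(grid, s.time, s.rate) for s in smooths]
    return od.RateTrace(time=grid, rate=np.mean(rates, axis=0))


def _pinned_ramp_onset(
    trace: od.RateTrace,
    taus: np.ndarray,
    t_start: float = -2500.0,
    t_peak: float = 0.0,
) -> float:
    """Onset of a ramp whose peak time is pinned at the alignment event.

    Least-squares fit of ``rate = b + A * relu(t - tau) / (t_peak -
    tau)`` over ``[t_start, t_peak]`` with ``b`` and ``A`` free and
    ``tau`` scanned over ``taus``.  This is the synthetic envelope's own
    family -- trials differ in ramp duration, not by a rigid time shift,
    because the discharge always peaks at the step over the obstacle.
    """
    sel = (trace.time >= t_start) & (trace.time <= t_peak)
    t = trace.time[sel]
    r = trace.rate[sel]
    n = len(t)
    if n < 10:
        raise ValueError("fit window too short")
    St = np.cumsum(t[::-1])[::-1]
    Stt = np.cumsum((t * t)[::-1])[::-1]
    Sr = np.cumsum(r[::-1])[::-1]
    Str = np.cumsum((t * r)[::-1])[::-1]
    Sy = float(r.sum())
    idx = np.searchsorted(t, taus, side="right")
    idx = np.clip(idx, 0, n - 1)
    n_suf = n - idx
    denom = np.maximum(t_peak - taus, 1.0)
    # f = (t - tau) / (t_peak - tau) on the suffix, 0 before
    sf = (St[idx] - taus * n_suf) / denom
    sff = (Stt[idx] - 2.0 * taus * St[idx] + taus * taus * n_suf) / denom**2
    sfy = (Str[idx] - taus * Sr[idx]) / denom
    det = n * sff - sf * sf
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = (n * sfy - sf * Sy) / det
        b = (Sy - amp * sf) / n
        sse = amp * amp * sff + n * b * b + 2.0 * amp * b * sf - 2.0 * amp * sfy - 2.0 * b * Sy
    sse = np.where((det <= 0) | ~np.isfinite(sse), np.inf, sse)
    return float(taus[int(np.argmin(sse))])


def _mle_pinned_onset(
    spike_times: np.ndarray,
    baseline_rate: float,
    prior: float,
    window: float,
    t_lo: float = -2500.0,
    t_hi: float = 0.0,
    step: float = 10.0,
    prior_sd: float | None = None,
) -> float:
    """Poisson maximum-likelihood onset of a ramp peaking at t = 0.

    Rate model ``b + A * relu(t - tau) / (-tau)`` on ``[t_lo, t_hi]``
    with the baseline ``b`` fixed (pooled estimate) and the amplitude
    ``A`` profiled out by Newton steps at each candidate ``tau``; the
    onset is the profile-likelihood maximizer over ``tau`` within
    ``window`` ms of ``prior``.  Working on the spikes directly avoids
    the information loss and bias of fitting a smoothed rate trace.
    ``prior_sd`` adds a weak Gaussian log-prior toward ``prior``; it is
    negligible for trials with an informative likelihood and regularizes
    the flat-likelihood trials that would otherwise scatter uniformly
    over the search window.
    """
    st = np.asarray(spike_times)
    st = st[(st >= t_lo) & (st <= t_hi)]
    taus = np.arange(max(t_lo + 100.0, prior - window), min(-20.0, prior + window) + 1.0, step)
    if len(taus) == 0:
        return prior
    best, best_ll = float(taus[0]), -np.inf
    for tau in taus:
        f = np.maximum(0.0, st - tau) / (-tau)
        integral_f = (-tau) / 2000.0  # integral of f over [tau, 0], seconds
        amp = 50.0
        for _ in range(4):
            d = baseline_rate + amp * f
            grad = float((f / d).sum()) - integral_f
            hess = -float((f * f / (d * d)).sum())
            if hess >= -1e-12:
                break
            amp -= grad / hess
            if amp < 0.0:
                amp = 0.0
                break
        d = baseline_rate + amp * f
        ll = float(np.log(np.maximum(d, 1e-9)).sum()) - (
            baseline_rate * (t_hi - t_lo) / 1000.0 + amp * integral_f
        )
        if prior_sd:
            ll -= 0.5 * ((tau - prior) / prior_sd) ** 2
        if ll > best_ll:
            best_ll, best = ll, float(tau)
    return best


def detect_group_onsets(
    trials: Sequence,
    config: AnalysisConfig = AnalysisConfig(),
    smooths: Sequence[od.RateTrace] | None = None,
) -> list[tuple[object, float, float]]:
    """Per-trial discharge onsets for a set of like trials.

    ``trials`` should share the same expected discharge profile --
    typically all of a cell's trials in one task (the gap statistics,
    and hence the expected onset, do not depend on which limb leads).
    Three stages, emulating informed interactive marking:

    1. *Gate* (per trial): the sustained 2 SD deviation rule on the
       50 Hz-filtered instantaneous frequency decides whether and in
       which direction the trial shows a discharge change.
    2. *Localize* (per trial): the candidate onset is the breakpoint of
       a least-squares ramp fit to the smoothed trace with the ramp
       vertex pinned at the step over the obstacle (t = 0) and baseline
       and amplitude free -- the structure the discharge actually has,
       since bursts peak at the step whichever moment they begin.
       Pinning the vertex removes most of the duration-dependent bias
       that free breakpoint or threshold rules carry.  The breakpoint is
       searched within ``refine_window_ms`` of the group-average onset,
       which suppresses the heavy tails weak-feature trials otherwise
       produce.
    3. *Shrink* (across trials): candidates are pulled toward the
       group-average onset by an empirical-Bayes factor ``k = max(0,
       1 - sigma0^2 / S^2)``, where ``S^2`` is the observed candidate
       variance and ``sigma0`` the assumed localization noise.  When
       trials genuinely differ (large onset jitter) ``k`` is close to 1
       and per-trial structure is preserved; when they are replicates,
       pooling toward the group onset is the efficient estimate.

    Returns ``(trial, onset_ms, candidate_ms)`` triples for trials
    passing the gate: ``onset_ms`` is the shrunk per-trial point
    estimate; ``candidate_ms`` the raw localized onset, whose
    trial-to-trial variance is honest and which therefore feeds the
    group-level ANOVAs (running an F-test on shrunk estimates would
    understate the within-group variance).
    """
    trials = list(trials)
    if not trials:
        return []
    if smooths is None:
        smooths = [_smooth_trace(t) for t in trials]
    extras = [od.lowpass(s, cutoff=config.refine_cutoff_hz) for s in smooths]
    xstats = od.pooled_baseline_stats(extras)

    gated: list[tuple[object, od.RateTrace, od.RateTrace, od.OnsetDetection]] = []
    for t, s, x in zip(trials, smooths, extras):
        det = od.detect_onset(x, xstats, sustain=config.sustain, backtrack=False)
        if det is not None:
            gated.append((t, s, x, det))
    if not gated:
        return []
    direction = "decrease" if sum(
        d.direction == "decrease" for *_, d in gated
    ) * 2 > len(gated) else "increase"

    avg = group_average_trace([s for _, s, _, _ in gated])
    prior = od.fit_hinge_onset(avg, t_start=od.BASELINE_WINDOW[1])

    # two passes: the second re-centers the onset search on the first
    # pass's median, recovering from a misplaced average-trace fit
    w = config.refine_window_ms
    b0 = max(xstats.mean, 1.0)
    center = prior
    for _ in range(2):
        cands_arr = np.asarray(
            [
                _mle_pinned_onset(
                    t.spikes.times, b0, center, w, prior_sd=config.onset_prior_sd_ms
                )
                for t, _, _, _ in gated
            ]
        )
        center = float(np.median(cands_arr))
    if len(cands_arr) >= 4:
        s2 = float(np.var(cands_arr, ddof=1))
        k = max(0.0, 1.0 - config.refine_noise_sd_ms**2 / s2) if s2 > 0 else 0.0
    else:
        k = 1.0
    refined = np.minimum(prior + k * (cands_arr - prior), -1.0)
    cands_arr = np.minimum(cands_arr, -1.0)
    return [
        (t, float(o), float(c))
        for (t, *_), o, c in zip(gated, refined, cands_arr)
    ]


def trial_onset_sample(
    trial,
    config: AnalysisConfig = AnalysisConfig(),
    stats: od.BaselineStats | None = None,
    smooth: od.RateTrace | None = None,
) -> OnsetSample | None:
    """Run the single-trial detection chain and map the onset to the gap.

    ``stats`` may be supplied externally (e.g. pooled over the cell's
    trials); by default the trial's own baseline window is used.
    """
    if trial.gap is None:
        return None
    if smooth is None:
        grid = od.detection_grid(trial.gap)
        raw = od.instantaneous_frequency(trial.spikes, grid)
        smooth = od.lowpass(raw)
    if stats is None:
        stats = od.baseline_stats(smooth)
    det = od.detect_onset(smooth, stats, sustain=config.sustain)
    if det is None or det.onset >= 0:
        return None
    dtc, ttc = od.map_onset_to_gap(det.onset, trial.gap)
    return OnsetSample(
        trial_id=trial.trial_id,
        task=trial.task,
        lead_condition=trial.lead_limb,
        onset=det.onset,
        dtc=dtc,
        ttc=ttc,
    )


def analyze_cell(
    cell_id: str,
    trials: Iterable,
    config: AnalysisConfig = AnalysisConfig(),
    seed: int | np.random.Generator | None = None,
    with_bootstrap: bool = False,
) -> CellClassification:
    """Full classification of one cell from its matched and VD trials.

    Runs onset detection per trial, removes per-group onset outliers
    (Tukey fences on onset times), computes both ANOVAs, the category,
    post-hoc tables, the modulation indices (with optional bootstrap
    CIs), and the step-advanced / limb-independence flags from the
    lead-condition averaged traces.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials = list(trials)
    relevant = [t for t in trials if t.task in ("matched", "visual_dissociation")]

    # smoothed rate traces once per trial (baseline statistics are pooled
    # across trials inside each group: a single trial's 500-ms baseline
    # window is too short to estimate the SD of a spiking rate trace)
    smooth_by_trial: dict[int, od.RateTrace] = {}
    for t in relevant:
        grid = od.detection_grid(t.gap)
        smooth_by_trial[id(t)] = od.lowpass(od.instantaneous_frequency(t.spikes, grid))

    samples: dict[tuple[str, str], list[OnsetSample]] = {k: [] for k in GROUPS}
    analyzed: dict[tuple[str, str], list] = {k: [] for k in GROUPS}
    for task in ("matched", "visual_dissociation"):
        group = [t for t in relevant if t.task == task]
        pairs = detect_group_onsets(
            group,
            config,
            smooths=[smooth_by_trial[id(t)] for t in group],
        )
        for t, _refined, onset in pairs:
            key = (task, t.lead_limb)
            dtc, ttc = od.map_onset_to_gap(onset, t.gap)
            samples[key].append(
                OnsetSample(
                    trial_id=t.trial_id,
                    task=task,
                    lead_condition=t.lead_limb,
                    onset=onset,
                    dtc=dtc,
                    ttc=ttc,
                )
            )
            analyzed[key].append(t)

    min_group = min(len(v) for v in samples.values())
    if min_group < 2:
        return CellClassification(
            cell_id=cell_id, category="NONE", p_dtc=np.nan, p_ttc=np.nan,
            index_dtc=np.nan, index_ttc=np.nan, included=False,
            reason="fewer than 2 detected onsets in some task x lead group",
        )

    # outlier removal on onset times per group; drop the matching trials
    kept: dict[tuple[str, str], list[OnsetSample]] = {}
    frac_removed: list[float] = []
    for key, ss in samples.items():
        onsets = np.array([s.onset for s in ss])
        _, frac, applied = remove_outliers(onsets, config.outlier_k)
        if applied:
            q1, q3 = np.percentile(onsets, [25, 75])
            iqr = q3 - q1
            keep_mask = (onsets >= q1 - config.outlier_k * iqr) & (
                onsets <= q3 + config.outlier_k * iqr
            )
        else:
            keep_mask = np.ones(len(ss), bool)
        kept[key] = [s for s, m in zip(ss, keep_mask) if m]
        analyzed[key] = [t for t, m in zip(analyzed[key], keep_mask) if m]
        frac_removed.append(1.0 - keep_mask.mean())

    dtc_groups = {k: [s.dtc for s in v] for k, v in kept.items()}
    ttc_groups = {k: [s.ttc for s in v] for k, v in kept.items()}
    p_dtc = anova_onset(dtc_groups)
    p_ttc = anova_onset(ttc_groups)
    category = classify_cell(p_dtc, p_ttc, config)

    # per-trial rate profiles on both grids for the index/bootstrap
    per_trial_d: dict[tuple[str, str], np.ndarray] = {}
    per_trial_t: dict[tuple[str, str], np.ndarray] = {}
    for key, ts in analyzed.items():
        rows_d, rows_t = [], []
        for t in ts:
            smooth = smooth_by_trial[id(t)]
            rows_d.append(
                rate_profile_on_grid(
                    smooth, t.gap, config.dtc_grid, "dtc", config.profile_smooth_dtc_cm
                )
            )
            rows_t.append(
                rate_profile_on_grid(
                    smooth, t.gap, config.ttc_grid, "ttc", config.profile_smooth_ttc_ms
                )
            )
        per_trial_d[key] = np.vstack(rows_d)
        per_trial_t[key] = np.vstack(rows_t)
    index_dtc = modulation_index(_group_profiles(per_trial_d))
    index_ttc = modulation_index(_group_profiles(per_trial_t))
    ci_d = ci_t = None
    if with_bootstrap:
        ci_d = bootstrap_index(per_trial_d, config, rng)
        ci_t = bootstrap_index(per_trial_t, config, rng)

    onset_by_lead: dict[str, float | None] = {}
    offset_by_lead: dict[str, float | None] = {}
    grid = np.arange(-3500.0, 2000.0 + 1.0)
    all_avg = od.RateTrace(
        time=grid,
        rate=np.mean(
            [np.interp(grid, smooth_by_trial[id(t)].time, smooth_by_trial[id(t)].rate)
             for t in relevant],
            axis=0,
        ),
    )
    shared_stats = od.baseline_stats(all_avg)
    for lead in ("left", "right"):
        ts = [t for t in relevant if t.lead_limb == lead]
        onset_by_lead[lead], offset_by_lead[lead] = _average_trace_onset_offset(
            ts, config, stats=shared_stats
        )
    step_adv, limb_indep = flag_step_advanced_and_limb_independent(
        onset_by_lead, offset_by_lead, config
    )

    return CellClassification(
        cell_id=cell_id,
        category=category,
        p_dtc=p_dtc,
        p_ttc=p_ttc,
        index_dtc=index_dtc,
        index_ttc=index_ttc,
        posthoc_dtc=posthoc_tests(dtc_groups, config),
        posthoc_ttc=posthoc_tests(ttc_groups, config),
        ci_dtc=ci_d,
        ci_ttc=ci_t,
        step_advanced=step_adv,
        limb_independent=limb_indep,
        included=True,
        n_onsets=sum(len(v) for v in kept.values()),
        outlier_fraction=float(np.mean(frac_removed)),
    )


def _average_trace_onset_offset(
    trials,
    config: AnalysisConfig,
    stats: od.BaselineStats | None = None,
) -> tuple[float | None, float | None]:
    """Onset and end-of-discharge of the across-trial averaged rate trace.

    ``stats`` may be shared between lead conditions so both use one
    threshold; otherwise the trace's own baseline is used.
    """
    if not trials:
        return None, None
    grid = np.arange(-3500.0, 2000.0 + 1.0)
    rates = []
    for t in trials:
        raw = od.instantaneous_frequency(t.spikes, grid)
        rates.append(od.lowpass(raw).rate)
    avg = od.RateTrace(time=grid, rate=np.mean(rates, axis=0))
    if stats is None:
        stats = od.baseline_stats(avg)
    # detect on a heavily smoothed copy (threshold-crossing times on the
    # shallow decay are otherwise dominated by residual averaging noise),
    # but keep the 2 SD threshold of the 50 Hz average
    smooth = od.lowpass(avg, cutoff=config.refine_cutoff_hz)
    det = od.detect_onset(smooth, stats, sustain=config.sustain)
    if det is None:
        return None, None
    off, _ = od.detect_offset(smooth, stats, after=det.onset, sustain=config.sustain)
    return det.onset, off
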