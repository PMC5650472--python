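import numpy as np
import pytest
from scipy import stats as sps

from gapclosure import cell_classification as cls
from gapclosure.cell_classification import (
    AnalysisConfig,
    analyze_cell,
    anova_onset,
    bootstrap_index,
    classify_cell,
    detect_group_onsets,
    flag_step_advanced_and_limb_independent,
    modulation_index,
    posthoc_tests,
    remove_outliers,
)

GROUPS = cls.GROUPS


class TestRemoveOutliers:
    def test_tukey_fences(self):
        kept, frac, applied = remove_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        # brute-force fences: Q1=2, Q3=4, IQR=2 -> [-1, 7]
        assert applied
        assert list(kept) == [1.0, 2.0, 3.0, 4.0]
        assert frac == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        kept, frac, applied = remove_outliers([5.0] * 6)
        assert list(kept) == [5.0] * 6 and frac == 0.0

    def test_small_samples_pass_through(self):
        kept, frac, applied = remove_outliers([1.0, 100.0, 2.0])
        assert not applied and len(kept) == 3


class TestAnova:
    def test_identical_groups_give_p_one(self):
        groups = {k: [5.0, 5.0, 5.0] for k in GROUPS}
        assert anova_onset(groups) == 1.0

    def test_separated_groups_significant(self):
        groups = dict(zip(GROUPS, [[10.0, 11.0, 12.0], [10.0, 12.0, 11.0],
                                   [30.0, 31.0, 29.0], [30.0, 29.0, 31.0]]))
        p = anova_onset(groups)
        # independent oracle: explicit sums of squares
        arrays = [np.array(v) for v in groups.values()]
        grand = np.concatenate(arrays).mean()
        ss_b = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
        ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        f_stat = (ss_b / 3) / (ss_w / 8)
        p_oracle = float(sps.f.sf(f_stat, 3, 8))
        assert p == pytest.approx(p_oracle, rel=1e-9)
        assert p < 0.01

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            groups = {k: rng.normal(0.0, 1.0, 8) for k in GROUPS}
            ps.append(anova_onset(groups))
        frac = np.mean(np.array(ps) < 0.1)
        assert 0.04 < frac < 0.18

    def test_empty_group_raises_with_name(self):
        groups = {k: [1.0, 2.0] for k in GROUPS}
        groups[GROUPS[2]] = []
        with pytest.raises(ValueError, match="visual_dissociation"):
            anova_onset(groups)


class TestClassifyRule:
    @pytest.mark.parametrize(
        "p_dtc,p_ttc,expected",
        [
            (0.5, 0.001, "DTC"),   # constant distance, time shifts with task
            (0.001, 0.5, "TTC"),   # constant time, distance shifts with task
            (0.001, 0.001, "BOTH"),
            (0.5, 0.5, "NONE"),
            (0.01, 0.0099, "DTC"),  # boundary: alpha is strict
        ],
    )
    def test_quadrants(self, p_dtc, p_ttc, expected):
        assert classify_cell(p_dtc, p_ttc) == expected

    def test_partition_of_the_p_plane(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p1, p2 = rng.uniform(0, 1, 2)
            assert classify_cell(p1, p2) in {"DTC", "TTC", "BOTH", "NONE"}


class TestPosthoc:
    def test_identical_groups_nothing_significant(self):
        groups = {k: [5.0, 5.0, 5.0] for k in GROUPS}
        table = posthoc_tests(groups)
        assert len(table) == 6
        assert not any(row["significant"] for row in table)
        assert all(row["degenerate"] for row in table)

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(2)
        groups = {k: list(rng.normal(i * 0.5, 1.0, 10)) for i, k in enumerate(GROUPS)}
        for row in posthoc_tests(groups):
            assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 6))

    def test_task_contrast_labels(self):
        groups = {k: [1.0, 2.0, 3.0] for k in GROUPS}
        table = posthoc_tests(groups)
        n_task = sum(r["task_contrast"] for r in table)
        assert n_task == 4  # four of six pairs cross the task boundary


class TestModulationIndex:
    def test_identical_profiles_give_zero(self):
        prof = np.linspace(0.0, 10.0, 50)
        profiles = {k: prof.copy() for k in GROUPS}
        assert modulation_index(profiles) == pytest.approx(0.0, abs=1e-9)

    def test_sign_convention(self):
        # VD active over a larger span of the grid -> positive index
        x = np.arange(100.0)
        m = np.where(x < 40, 10.0, 0.0)
        v = np.where(x < 70, 10.0, 0.0)
        profiles = dict(zip(GROUPS, [m, m + 0.01, v, v + 0.01]))
        assert modulation_index(profiles) > 0.5

    def test_missing_group_raises(self):
        with pytest.raises(ValueError):
            modulation_index({GROUPS[0]: np.zeros(5)})


class TestBootstrap:
    def test_zero_variance_trials_degenerate_ci(self):
        prof = np.tile(np.linspace(0, 5, 30), (6, 1))
        per_trial = {k: prof.copy() for k in GROUPS}
        per_trial[GROUPS[2]] = per_trial[GROUPS[2]] + 1.0
        per_trial[GROUPS[3]] = per_trial[GROUPS[3]] + 1.0
        cfg = AnalysisConfig(n_bootstrap=50)
        lo, hi = bootstrap_index(per_trial, cfg, seed=0)
        assert lo == pytest.approx(hi)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        per_trial = {k: rng.normal(0, 1, (8, 30)) for k in GROUPS}
        cfg = AnalysisConfig(n_bootstrap=100)
        assert bootstrap_index(per_trial, cfg, seed=7) == bootstrap_index(
            per_trial, cfg, seed=7
        )


class TestFlags:
    def test_step_advanced_and_limb_independent(self):
        adv, indep = flag_step_advanced_and_limb_independent(
            {"left": -600.0, "right": -550.0}, {"left": 30.0, "right": 120.0}
        )
        assert adv and indep

    def test_late_onset_not_advanced(self):
        adv, _ = flag_step_advanced_and_limb_independent(
            {"left": -100.0, "right": -600.0}, {"left": 0.0, "right": 0.0}
        )
        assert not adv

    def test_large_offset_difference_not_independent(self):
        _, indep = flag_step_advanced_and_limb_independent(
            {"left": -600.0, "right": -600.0}, {"left": 0.0, "right": 300.0}
        )
        assert not indep


class TestEndToEnd:
    def test_small_session_classification(self, small_session):
        results = {}
        for spec in small_session.cells:
            c = analyze_cell(spec.cell_id, small_session.trials[spec.cell_id])
            results[spec.cell_id] = c
        # ideal cells at low jitter must classify correctly
        assert results["dtc"].category == "DTC"
        assert results["ttc"].category == "TTC"
        # index signs: DTC cell positive on the TTC axis, TTC cell negative
        # on the DTC axis, each near zero on its own axis
        assert results["dtc"].index_ttc > 0.3
        assert results["dtc"].index_ttc > results["dtc"].index_dtc + 0.3
        assert results["ttc"].index_dtc < -0.3
        assert results["ttc"].index_dtc < results["ttc"].index_ttc - 0.3
        # the synthetic envelope is step-advanced by construction
        assert results["dtc"].step_advanced

    def test_posthoc_task_contrast_for_dtc_cell(self, small_session):
        c = analyze_cell("dtc", small_session.trials["dtc"])
        # significant matched-vs-VD contrasts on the TTC axis ...
        sig_task_ttc = [
            r for r in c.posthoc_ttc if r["task_contrast"] and not r["lead_contrast"]
        ]
        assert any(r["significant"] for r in sig_task_ttc)
        # ... and none on the DTC axis
        assert not any(
            r["significant"]
            for r in c.posthoc_dtc
            if r["task_contrast"] and not r["lead_contrast"]
        )

    def test_detection_tracks_truth(self, small_session):
        trials = [
            t for t in small_session.trials["dtc"] if t.task == "matched"
        ]
        pairs = detect_group_onsets(trials)
        assert len(pairs) >= 0.8 * len(trials)
        errs = np.array([cand - t.truth_onset for t, _, cand in pairs])
        assert np.median(np.abs(errs)) < 250.0

    def test_limb_independence_with_ample_trials(self):
        # the envelope ends at the lead limb's Br whichever limb leads, so
        # with enough trials the averaged end-of-discharge must agree
        from gapclosure.synthetic_cells import CellSpec, SessionDesign, generate_session

        spec = CellSpec(cell_id="c", category="DTC", trigger_dtc_cm=30.0, onset_jitter_sd=50.0)
        design = SessionDesign(
            n_matched_per_lead=20, n_vd_per_lead=20, accel_conditions=(), n_unobstructed=5
        )
        flags = []
        for seed in (7, 8, 9):
            sess = generate_session([spec], design, seed=seed)
            c = analyze_cell("c", sess.trials["c"])
            flags.append(bool(c.limb_independent))
        assert sum(flags) >= 2

    def test_step_related_cell_is_not_step_advanced(self):
        # a cell that merely modulates with every step cycle has no
        # obstacle-advanced ramp and must not earn the step-advanced flag
        from gapclosure.synthetic_cells import CellSpec, SessionDesign, generate_session

        spec = CellSpec(cell_id="s", category="STEP_RELATED", trigger_dtc_cm=None)
        design = SessionDesign(
            n_matched_per_lead=10, n_vd_per_lead=10, accel_conditions=(), n_unobstructed=5
        )
        sess = generate_session([spec], design, seed=11)
        c = analyze_cell("s", sess.trials["s"])
        assert c.step_advanced is not True
        assert c.category in {"NONE", "BOTH"} or not c.included

    def test_insufficient_trials_excluded(self, small_session):
        trials = small_session.trials["dtc"][:3]
        c = analyze_cell("dtc", trials)
        assert not c.included
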