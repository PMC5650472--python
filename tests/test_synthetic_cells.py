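import numpy as np
import pytest
from scipy import stats as sps

from gapclosure.onset_detection import RateTrace
from gapclosure.synthetic_cells import (
    CellSpec,
    SessionDesign,
    SpikeTrain,
    generate_session,
    rate_envelope,
    realize_trial,
    sample_spikes,
)
from gapclosure.task_kinematics import TaskConfig


def _clean_trial(spec, task, lead="left", seed=0):
    return realize_trial(
        spec, task, lead, trial_seed=seed, config=TaskConfig(), gait_jitter_sd=0.0
    )


class TestRateEnvelope:
    def test_distance_trigger_onsets_per_task(self):
        spec = CellSpec(cell_id="c", category="DTC", trigger_dtc_cm=30.0, onset_jitter_sd=0.0)
        t_m = _clean_trial(spec, "matched")
        t_v = _clean_trial(spec, "visual_dissociation")
        # 30 cm at 0.45 m/s is 667 ms out; at 0.3 m/s, 1000 ms
        assert t_m.truth_onset == pytest.approx(-30.0 / 0.045, abs=2.0)
        assert t_v.truth_onset == pytest.approx(-30.0 / 0.03, abs=2.0)
        # onset gap equals trigger * (1/v_vd - 1/v_matched)
        expected = 30.0 * (1.0 / 0.03 - 1.0 / 0.045)
        assert t_m.truth_onset - t_v.truth_onset == pytest.approx(expected, abs=3.0)

    def test_time_trigger_is_task_independent(self):
        spec = CellSpec(
            cell_id="c", category="TTC", trigger_dtc_cm=None,
            trigger_ttc_ms=600.0, onset_jitter_sd=0.0,
        )
        t_m = _clean_trial(spec, "matched")
        t_v = _clean_trial(spec, "visual_dissociation")
        assert t_m.truth_onset == pytest.approx(-600.0, abs=2.0)
        assert t_v.truth_onset == pytest.approx(-600.0, abs=2.0)

    def test_envelope_shape(self):
        spec = CellSpec(cell_id="c", category="DTC", trigger_dtc_cm=30.0, onset_jitter_sd=0.0)
        trial = _clean_trial(spec, "matched")
        env, onset = rate_envelope(spec, trial, seed=0)
        r_at = lambda t: float(np.interp(t, env.time, env.rate))
        assert r_at(onset - 200.0) == pytest.approx(spec.baseline_rate)
        assert r_at(0.0) == pytest.approx(spec.peak_rate, rel=0.02)
        # exponential decay back toward baseline
        assert r_at(3.0 * spec.decay_time) < spec.baseline_rate + 0.1 * (
            spec.peak_rate - spec.baseline_rate
        )

    def test_acceleration_steepens_the_ramp(self):
        # the episode delays the trigger crossing while the peak stays at
        # the step, so the onset-to-peak slope must increase
        spec = CellSpec(cell_id="c", category="DTC", trigger_dtc_cm=30.0, onset_jitter_sd=0.0)
        t_v = _clean_trial(spec, "visual_dissociation")
        t_a = _clean_trial(spec, "accel_1L")
        slope = lambda t: (spec.peak_rate - spec.baseline_rate) / (-t.truth_onset)
        assert t_a.truth_onset > t_v.truth_onset
        assert slope(t_a) > slope(t_v)

    def test_unobstructed_trials_stay_at_baseline(self):
        spec = CellSpec(cell_id="c", category="DTC", trigger_dtc_cm=30.0)
        trial = _clean_trial(spec, "unobstructed")
        assert trial.truth_onset is None
        env, onset = rate_envelope(spec, trial, seed=0)
        assert onset is None
        assert np.allclose(env.rate, spec.baseline_rate)

    def test_step_related_cells_follow_the_cycle(self):
        spec = CellSpec(cell_id="c", category="STEP_RELATED", trigger_dtc_cm=None)
        trial = _clean_trial(spec, "matched")
        env, onset = rate_envelope(spec, trial, seed=0)
        assert onset is None
        r_at = lambda t: float(np.interp(t, env.time, env.rate))
        # peaks at each lead-limb Br onset, troughs half a cycle away
        assert r_at(0.0) == pytest.approx(spec.peak_rate, rel=0.01)
        assert r_at(-1000.0) == pytest.approx(spec.peak_rate, rel=0.01)
        assert r_at(-500.0) == pytest.approx(spec.baseline_rate, rel=0.05)


class TestSampleSpikes:
    def test_zero_envelope(self):
        env = RateTrace(time=np.arange(0.0, 1000.0), rate=np.zeros(1000))
        assert len(sample_spikes(env, seed=0)) == 0

    def test_poisson_count_statistics(self):
        env = RateTrace(time=np.arange(0.0, 10_001.0), rate=np.full(10_001, 20.0))
        counts = [len(sample_spikes(env, seed=s)) for s in range(300)]
        # mean within 3 standard errors of the Poisson expectation
        assert np.mean(counts) == pytest.approx(200.0, abs=3 * np.sqrt(200.0 / 300) * 10)
        assert abs(np.mean(counts) - 200.0) < 3.0 * np.sqrt(200.0) / np.sqrt(300) + 2.0

    def test_rate_doubling_doubles_counts(self):
        t = np.arange(0.0, 20_001.0)
        n1 = np.mean([len(sample_spikes(RateTrace(t, np.full_like(t, 10.0)), seed=s)) for s in range(50)])
        n2 = np.mean([len(sample_spikes(RateTrace(t, np.full_like(t, 20.0)), seed=s)) for s in range(50)])
        assert n2 / n1 == pytest.approx(2.0, rel=0.1)

    def test_refractory_and_order(self):
        env = RateTrace(time=np.arange(0.0, 5001.0), rate=np.full(5001, 80.0))
        train = sample_spikes(env, seed=1)
        assert np.all(np.diff(train.times) >= 1.0)

    def test_determinism(self):
        env = RateTrace(time=np.arange(0.0, 2001.0), rate=np.full(2001, 30.0))
        a = sample_spikes(env, seed=42)
        b = sample_spikes(env, seed=42)
        assert np.array_equal(a.times, b.times)

    def test_baseline_counts_are_poisson(self):
        # chi-square goodness of fit of per-window spike counts
        env = RateTrace(time=np.arange(0.0, 501.0), rate=np.full(501, 10.0))
        counts = np.array([len(sample_spikes(env, seed=s)) for s in range(1000)])
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = sps.poisson.pmf(np.arange(kmax + 1), mu=5.0) * len(counts)
        # pool sparse tail bins
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        exp *= obs.sum() / exp.sum()
        p = sps.chisquare(obs, exp).pvalue
        assert p > 0.01


class TestGenerateSession:
    def test_default_design_trial_count(self):
        assert SessionDesign().n_trials == 62
        assert 40 <= SessionDesign().n_trials <= 80

    def test_session_contents(self, small_session):
        for cell in small_session.cells:
            trials = small_session.trials[cell.cell_id]
            assert len(trials) == small_session.design.n_trials
            for t in trials:
                assert np.all(np.diff(t.spikes.times) > 0)
                if t.truth_onset is not None:
                    assert t.gap.time[0] <= t.truth_onset <= 0.0
                if t.task == "unobstructed":
                    assert t.gap is None and t.truth_onset is None

    def test_inclusion_violation_is_flagged(self):
        spec = CellSpec(cell_id="c", category="DTC", trigger_dtc_cm=30.0)
        design = SessionDesign(n_unobstructed=0, accel_conditions=())
        with pytest.warns(UserWarning):
            sess = generate_session([spec], design, seed=0)
        assert not sess.meets_inclusion

    def test_spike_train_validates_order(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([3.0, 2.0, 5.0]))

    def test_cellspec_validation(self):
        with pytest.raises(ValueError):
            CellSpec(cell_id="x", category="DTC", trigger_dtc_cm=None)
        with pytest.raises(ValueError):
            CellSpec(cell_id="x", baseline_rate=60.0, peak_rate=10.0)
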