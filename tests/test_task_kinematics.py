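import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapclosure.task_kinematics import (
    AccelerationProfile,
    DriftModel,
    TaskConfig,
    gait_timeline,
    gap_trace,
    obstacle_speed_at,
    ttc_at_distance,
)


class TestTtcAtDistance:
    def test_matched_and_dissociated_gap(self):
        # 45 cm is 1000 ms away at the matched speed but 1500 ms at the slowed one
        assert ttc_at_distance(45.0, 0.45) == pytest.approx(1000.0)
        assert ttc_at_distance(45.0, 0.3) == pytest.approx(1500.0)
        assert ttc_at_distance(0.0, 0.7) == 0.0

    def test_rejects_nonpositive_closure(self):
        with pytest.raises(ValueError):
            ttc_at_distance(10.0, 0.0)
        with pytest.raises(ValueError):
            ttc_at_distance(-1.0, 0.45)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        dtc=st.floats(0.1, 300.0),
        v=st.floats(0.05, 2.0),
        c=st.floats(0.1, 10.0),
    )
    def test_scaling(self, dtc, v, c):
        # doubling both distance and speed leaves the time unchanged
        base = ttc_at_distance(dtc, v)
        assert ttc_at_distance(c * dtc, c * v) == pytest.approx(base, rel=1e-9)


class TestObstacleSpeed:
    def test_piecewise_profile(self):
        p = AccelerationProfile()
        assert obstacle_speed_at(-10.0, p, 0.0) == pytest.approx(0.3)
        assert obstacle_speed_at(225.0, p, 0.0) == pytest.approx(0.475)
        assert obstacle_speed_at(450.0, p, 0.0) == pytest.approx(0.65)
        assert obstacle_speed_at(900.0, p, 0.0) == pytest.approx(0.3)
        assert obstacle_speed_at(2000.0, p, 0.0) == pytest.approx(0.3)

    def test_extra_closure_over_episode(self):
        # independent quadrature of (v(t) - v_start) over the full episode
        p = AccelerationProfile()
        t = np.linspace(0.0, 900.0, 9001)
        v = obstacle_speed_at(t, p, 0.0)
        extra_cm = np.trapezoid((v - p.v_start) * 0.1, t)  # m/s -> cm/ms
        assert extra_cm == pytest.approx(15.75, abs=0.01)

    def test_invalid_profile(self):
        with pytest.raises(ValueError):
            AccelerationProfile(v_start=0.7, v_peak=0.65)


class TestGaitTimeline:
    def test_regular_alternation(self):
        cfg = TaskConfig()
        tl = gait_timeline(cfg, n_steps=12, jitter_sd=0.0, lead_limb="left")
        onsets = tl.br_onsets()
        assert np.allclose(onsets, -500.0 * np.arange(12)[::-1])
        assert tl.br_onsets("left")[-1] == 0.0
        # limbs alternate: same-limb onsets one full cycle apart
        assert np.allclose(np.diff(tl.br_onsets("left")), 1000.0)

    def test_right_lead_ends_on_right(self):
        tl = gait_timeline(TaskConfig(), n_steps=8, jitter_sd=0.0, lead_limb="right")
        assert tl.br_onsets("right")[-1] == 0.0

    def test_obstacle_spacing_spans_about_thirteen_steps(self):
        # 3 m at the matched closure speed lasts 6667 ms, ~13 steps of 500 ms
        cfg = TaskConfig()
        duration_ms = cfg.obstacle_spacing / cfg.obstacle_speed * 1000.0
        n_steps = duration_ms / cfg.step_period
        assert 12 <= round(n_steps) <= 14

    def test_jitter_keeps_order(self):
        tl = gait_timeline(TaskConfig(), n_steps=12, jitter_sd=30.0, lead_limb="left", seed=0)
        assert np.all(np.diff(tl.br_onsets()) > 0)


class TestGapTrace:
    def test_uniform_motion(self, matched_config):
        tl = gait_timeline(matched_config, n_steps=12, jitter_sd=0.0, lead_limb="left")
        g = gap_trace(matched_config, tl, initial_dtc=90.0)
        assert g.time[0] == pytest.approx(-2000.0)
        assert g.dtc[0] == pytest.approx(90.0, abs=0.1)
        assert g.dtc[-1] == pytest.approx(0.0, abs=1e-9)
        assert g.ttc[-1] == pytest.approx(0.0, abs=1e-9)
        # TTC decreases linearly under uniform motion
        assert np.allclose(np.diff(g.ttc), -1.0)

    def test_ttc_consistent_with_distance_over_speed(self, vd_gap):
        assert np.allclose(vd_gap.ttc, vd_gap.dtc / 0.03, atol=1e-6)

    def test_dtc_strictly_decreasing_with_modest_drift(self):
        cfg = TaskConfig(drift=DriftModel(amplitude_cm=2.0, correlation_ms=1000.0))
        tl = gait_timeline(cfg, n_steps=12, jitter_sd=0.0, lead_limb="left")
        g = gap_trace(cfg, tl, initial_dtc=120.0, seed=7)
        assert np.all(np.diff(g.dtc) < 0)

    def test_acceleration_reaches_trigger_distance(self):
        # with the 1L episode the obstacle is ~39 cm away at the episode start
        accel = AccelerationProfile(trigger_condition="1L")
        cfg = TaskConfig(obstacle_speed=0.3, acceleration=accel)
        tl = gait_timeline(cfg, n_steps=12, jitter_sd=0.0, lead_limb="left")
        g = gap_trace(cfg, tl, initial_dtc=200.0)
        t_trig = tl.acceleration_trigger_time(accel)
        assert t_trig == pytest.approx(-800.0)
        assert g.dtc_at(t_trig) == pytest.approx(39.4, abs=0.5)

    def test_acceleration_shortens_final_approach(self):
        # time from a fixed 30 cm down to contact shrinks under the episode
        base_cfg = TaskConfig(obstacle_speed=0.3)
        tl = gait_timeline(base_cfg, n_steps=12, jitter_sd=0.0, lead_limb="left")
        g0 = gap_trace(base_cfg, tl, initial_dtc=200.0)
        accel_cfg = TaskConfig(
            obstacle_speed=0.3, acceleration=AccelerationProfile(trigger_condition="1L")
        )
        g1 = gap_trace(accel_cfg, tl, initial_dtc=200.0)

        def time_from_30cm(g):
            idx = np.nonzero(g.dtc <= 30.0)[0][0]
            return -g.time[idx]

        assert time_from_30cm(g1) < time_from_30cm(g0)

    def test_episode_conserves_displacement(self):
        # before the episode the accelerated trace sits exactly 15.75 cm
        # farther out than the unperturbed one (backward-anchored frames)
        base_cfg = TaskConfig(obstacle_speed=0.3)
        tl = gait_timeline(base_cfg, n_steps=12, jitter_sd=0.0, lead_limb="left")
        g0 = gap_trace(base_cfg, tl, initial_dtc=200.0)
        accel_cfg = TaskConfig(
            obstacle_speed=0.3, acceleration=AccelerationProfile(trigger_condition="2L")
        )
        g1 = gap_trace(accel_cfg, tl, initial_dtc=200.0)
        t_trig = tl.acceleration_trigger_time(accel_cfg.acceleration)
        t_before = t_trig - 100.0
        assert g1.dtc_at(t_before) - g0.dtc_at(t_before) == pytest.approx(15.75, abs=0.05)

    def test_bad_initial_distance(self, matched_config):
        tl = gait_timeline(matched_config, n_steps=12, jitter_sd=0.0, lead_limb="left")
        with pytest.raises(ValueError):
            gap_trace(matched_config, tl, initial_dtc=0.0)

    def test_interpolation_guard(self, matched_gap):
        with pytest.raises(ValueError):
            matched_gap.dtc_at(matched_gap.time[0] - 100.0)


def test_config_invariants():
    with pytest.raises(ValueError):
        TaskConfig(treadmill_speed=0.0)
    with pytest.raises(ValueError):
        TaskConfig(visibility_distance=4.0)  # beyond the obstacle spacing
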