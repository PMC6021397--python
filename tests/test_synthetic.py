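"""Synthetic worm generator: determinism, bout structure, rendering ties."""

import numpy as np
import pytest

from wormsleep import (
    BehaviorParams,
    ChamberGeometry,
    DetectorParams,
    SimulatedWorm,
    WormState,
    batch_detect,
    render_frame,
    simulate_behavior,
    simulate_step,
    standard_fixture,
)
from wormsleep.errors import ParameterError
from wormsleep.synthetic import MOTION_BOUT, SLEEP_BOUT, WAKE


def sleeping_state(response_prob=1.0):
    return WormState(
        nose_xy_um=np.array([95.0, 95.0]), heading_rad=0.3,
        behavioral_state=SLEEP_BOUT, pumping=False,
        response_prob=response_prob, bout_time_left_s=50.0,
    )


def midlethargus_kwargs():
    params = BehaviorParams()
    t = 0.5 * (params.lethargus_start_s + params.lethargus_end_s)
    return dict(params=params, t_s=t, dt=1.0)


class TestSimulateStep:
    def test_tap_with_certain_response_wakes_into_motion_bout(self):
        rng = np.random.default_rng(0)
        new = simulate_step(sleeping_state(1.0), True, rng=rng,
                            **midlethargus_kwargs())
        assert new.behavioral_state == MOTION_BOUT
        assert new.response_prob == pytest.approx(0.8)  # one habituation step

    def test_tap_with_zero_response_is_ignored(self):
        rng = np.random.default_rng(0)
        new = simulate_step(sleeping_state(0.0), True, rng=rng,
                            **midlethargus_kwargs())
        assert new.behavioral_state == SLEEP_BOUT
        assert new.response_prob == 0.0

    def test_sleep_bout_has_exactly_zero_displacement(self):
        rng = np.random.default_rng(0)
        state = sleeping_state()
        new = simulate_step(state, False, rng=rng, **midlethargus_kwargs())
        np.testing.assert_array_equal(new.nose_xy_um, state.nose_xy_um)
        assert new.pumping is False

    def test_outside_lethargus_worm_wakes_and_pumps(self):
        params = BehaviorParams()
        rng = np.random.default_rng(0)
        new = simulate_step(sleeping_state(), False, params=params, rng=rng,
                            t_s=params.lethargus_end_s + 1.0, dt=1.0)
        assert new.behavioral_state == WAKE and new.pumping is True
        assert np.any(new.nose_xy_um != sleeping_state().nose_xy_um)

    def test_position_stays_inside_chamber(self):
        params = BehaviorParams()
        chamber = ChamberGeometry()
        rng = np.random.default_rng(7)
        state = WormState(nose_xy_um=np.array([1.0, 188.0]), heading_rad=2.0,
                          behavioral_state=WAKE, pumping=True, response_prob=1.0)
        for k in range(200):
            state = simulate_step(state, False, params, rng, t_s=float(k),
                                  dt=1.0, chamber=chamber)
            assert 0 <= state.nose_xy_um[0] <= chamber.side_um
            assert 0 <= state.nose_xy_um[1] <= chamber.side_um


class TestSimulateBehavior:
    def test_same_seed_gives_identical_traces(self):
        a = simulate_behavior(seed=4).to_frame()
        b = simulate_behavior(seed=4).to_frame()
        assert a.equals(b)

    def test_duration_must_cover_lethargus(self):
        with pytest.raises(ParameterError):
            simulate_behavior(duration_s=100.0)

    def test_sleep_fraction_matches_renewal_stationarity(self):
        """Long lethargus: fraction of sleep-bout frames near S/(S+M).

        For exponential bouts the delta-method s.e. of the time-average
        over k cycles is p(1-p)*sqrt(2/k)."""
        params = BehaviorParams(lethargus_start_s=100.0, lethargus_end_s=7100.0)
        bt = simulate_behavior(params=params, duration_s=7200.0, seed=1)
        frac = bt.sleep_fraction_in_lethargus()
        s, m = params.sleep_bout_mean_s, params.motion_bout_mean_s
        p = s / (s + m)
        k = 7000.0 / (s + m)
        se = p * (1 - p) * np.sqrt(2.0 / k)
        assert abs(frac - p) <= 3 * se

    def test_wake_speed_calibration(self):
        """Measured wake nose speed tracks the commanded 16 um/s mean.

        Wall reflections in the 190 um chamber fold the path, so the
        frame-to-frame displacement speed sits somewhat below the commanded
        path speed; it must stay in the same regime and well above the
        motion-bout speed."""
        bt = simulate_behavior(seed=2)
        pre = bt.state == WAKE
        steps = np.linalg.norm(np.diff(bt.nose_positions_um(), axis=0), axis=1)
        wake_speed = steps[pre[:-1] & pre[1:]].mean()
        assert 0.7 * 16.0 <= wake_speed <= 1.05 * 16.0
        motion = bt.state == MOTION_BOUT
        motion_speed = steps[motion[:-1] & motion[1:]].mean()
        assert motion_speed < wake_speed

    def test_habituation_is_exact_powers_of_decay(self):
        """response_prob after k answered trains = initial * decay^k."""
        params = BehaviorParams()
        rng = np.random.default_rng(0)
        state = sleeping_state(params.tap_response_prob_initial)
        answered = 0
        t = 0.5 * (params.lethargus_start_s + params.lethargus_end_s)
        for _ in range(4):
            state.behavioral_state = SLEEP_BOUT
            before = state.behavioral_state
            state = simulate_step(state, True, params, rng, t_s=t, dt=1.0)
            if state.behavioral_state == MOTION_BOUT and before == SLEEP_BOUT:
                answered += 1
            assert state.response_prob == pytest.approx(
                params.tap_response_prob_initial * params.habituation_decay ** answered
            )


class TestRendering:
    def test_default_chamber_renders_190_square(self):
        frame = render_frame(sleeping_state(), ChamberGeometry(),
                             BehaviorParams(noise_sigma=0.0))
        assert frame.pixels.shape == (190, 190)

    def test_zero_noise_rendering_is_deterministic(self):
        params = BehaviorParams(noise_sigma=0.0)
        a = render_frame(sleeping_state(), ChamberGeometry(), params)
        b = render_frame(sleeping_state(), ChamberGeometry(), params)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_blob_centroid_tracks_nose_position(self):
        params = BehaviorParams(noise_sigma=0.0, background=0.0)
        state = sleeping_state()
        state.nose_xy_um = np.array([60.25, 130.75])
        frame = render_frame(state, ChamberGeometry(), params)
        px = frame.pixels
        ys, xs = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
        cx = (xs * px).sum() / px.sum()
        cy = (ys * px).sum() / px.sum()
        assert cx == pytest.approx(60.25, abs=0.1)
        assert cy == pytest.approx(130.75, abs=0.1)

    def test_noise_calibration_noise_activity_well_below_wake(self):
        """Whole-frame noise-only activity must not drown the motion signal."""
        _, tr = standard_fixture(seed=0, duration_s=800.0)
        bt = simulate_behavior(seed=0, duration_s=800.0)
        wake = bt.state == WAKE
        wake_pairs = wake[:-1] & wake[1:]
        sleep = bt.state == SLEEP_BOUT
        sleep_pairs = sleep[:-1] & sleep[1:]
        wake_act = tr.values[wake_pairs[: len(tr.values)]].mean()
        noise_act = tr.values[sleep_pairs[: len(tr.values)]].mean()
        assert noise_act < 0.3 * wake_act


class TestGroundTruthConsistency:
    def test_zero_noise_sleep_bouts_have_zero_activity_and_wake_positive(self):
        bt, tr = standard_fixture(seed=0, noise_sigma=0.0)
        sleep = bt.state == SLEEP_BOUT
        pair_sleep = sleep[:-1] & sleep[1:]
        assert np.all(tr.values[pair_sleep[: len(tr.values)]] == 0.0)
        wake = bt.state == WAKE
        pair_wake = wake[:-1] & wake[1:]
        assert np.all(tr.values[pair_wake[: len(tr.values)]] > 0.0)

    def test_detector_defaults_flag_only_lethargus_on_clean_fixture(self):
        bt, tr = standard_fixture(seed=1, noise_sigma=0.0)
        decisions = batch_detect(tr, DetectorParams())
        wake = bt.state == WAKE
        for d in decisions:
            if d.asleep:
                assert not (wake[d.t] and wake[d.t + 1])

    def test_rendering_substream_does_not_perturb_behavior(self):
        from dataclasses import replace

        noisy = SimulatedWorm(seed=9)
        clean = SimulatedWorm(params=replace(BehaviorParams(), noise_sigma=0.0),
                              seed=9)
        for _ in range(300):
            noisy.step(False)
            clean.step(False)
        a, b = noisy.behavior_trace(), clean.behavior_trace()
        np.testing.assert_array_equal(a.x_um, b.x_um)
        assert list(a.state) == list(b.state)
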