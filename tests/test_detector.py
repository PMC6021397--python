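"""Dual dynamic threshold: criterion algebra, streaming vs batch, gates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormsleep import (
    DetectorParams,
    GlobalStats,
    batch_detect,
    detect_stream,
    init_detector,
    notify_stimulus,
    sleep_criterion,
    step_detector,
)
from wormsleep.activity import ActivitySample
from wormsleep.detector import (
    decisions_to_frame,
    mean_threshold,
    mean_threshold_subtractive,
)
from wormsleep.errors import (
    ContractError,
    InsufficientInputError,
    ParameterError,
    SequencingError,
)
from conftest import make_trace


def stats_of(values):
    s = GlobalStats()
    for v in values:
        s.push(v)
    return s


class TestParams:
    def test_reference_defaults(self):
        p = DetectorParams()
        assert (p.window_w, p.k_std, p.k_mean) == (5, 40.0, 1.5)
        assert p.refractory_frames == p.window_w

    @pytest.mark.parametrize(
        "kwargs, offending",
        [
            ({"k_mean": 1.0}, "k_mean"),
            ({"window_w": 1}, "window_w"),
            ({"k_std": 0.0}, "k_std"),
            ({"warmup_frames": 2}, "warmup_frames"),
        ],
    )
    def test_invalid_params_name_the_field(self, kwargs, offending):
        with pytest.raises(ParameterError, match=offending):
            DetectorParams(**kwargs)


class TestGlobalStats:
    def test_small_batch_oracle(self):
        s = stats_of([2, 4, 6])
        assert s.mean == pytest.approx(4.0)
        assert s.std == pytest.approx(np.std([2, 4, 6]))  # population, ~1.63299
        assert s.min == 2

    def test_single_value(self):
        s = stats_of([3.5])
        assert (s.mean, s.std, s.min) == (3.5, 0.0, 3.5)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=200))
    def test_welford_matches_batch_recomputation(self, values):
        s = stats_of(values)
        arr = np.asarray(values)
        assert s.mean == pytest.approx(arr.mean(), rel=1e-9, abs=1e-9)
        assert s.std == pytest.approx(arr.std(), rel=1e-9, abs=1e-6)
        assert s.min == arr.min()

    @given(st.lists(st.floats(0, 1e3), min_size=2, max_size=50), st.randoms())
    def test_order_invariance(self, values, pyrandom):
        shuffled = list(values)
        pyrandom.shuffle(shuffled)
        a, b = stats_of(values), stats_of(shuffled)
        assert a.mean == pytest.approx(b.mean, rel=1e-9, abs=1e-9)
        assert a.std == pytest.approx(b.std, rel=1e-6, abs=1e-6)
        assert a.min == b.min

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            GlobalStats().push(-1.0)


class TestSleepCriterion:
    def test_quiet_window_after_active_history(self):
        # 20 x 100 then 5 x 0: global mean 80, min 0; bound (0.5*80+0)/1.5
        stats = stats_of([100.0] * 20 + [0.0] * 5)
        assert mean_threshold(stats, 1.5) == pytest.approx(80 / 3)
        assert sleep_criterion([0] * 5, stats, DetectorParams()) is True

    def test_constant_trace_holds_by_equality(self):
        # documented degeneracy of the inclusive comparisons
        stats = stats_of([7.0] * 30)
        assert sleep_criterion([7.0] * 5, stats, DetectorParams()) is True

    def test_oscillating_window_fails_std_bound(self):
        stats = stats_of([0.0, 200.0] * 10)
        local = [0.0, 200.0, 0.0, 200.0, 0.0]
        assert float(np.std(local)) > stats.std / 40
        assert sleep_criterion(local, stats, DetectorParams()) is False

    def test_wrong_window_length_is_contract_error(self):
        stats = stats_of(range(10))
        with pytest.raises(ContractError):
            sleep_criterion([1, 2, 3], stats, DetectorParams())

    @given(
        st.lists(st.floats(0, 1e4), min_size=5, max_size=5),
        st.lists(st.floats(0, 1e4), min_size=5, max_size=100),
        st.floats(1.01, 10.0),
    )
    def test_both_mean_bound_forms_agree(self, local, glob, k_mean):
        stats = stats_of(glob)
        lhs = float(np.mean(local))
        assert (lhs <= mean_threshold(stats, k_mean)) == (
            lhs <= mean_threshold_subtractive(stats, k_mean)
        ) or abs(mean_threshold(stats, k_mean) - lhs) < 1e-9 * max(1.0, lhs)

    @given(
        st.lists(st.floats(1.0, 1e4), min_size=5, max_size=5),
        st.lists(st.floats(0.0, 1e4), min_size=10, max_size=60),
        st.floats(0.0, 1.0),
    )
    def test_uniform_lowering_never_unsets_sleep(self, local, glob, frac):
        """Translating the local window down (std unchanged) keeps asleep."""
        params = DetectorParams()
        stats = stats_of(glob)
        if not sleep_criterion(local, stats, params):
            return
        delta = frac * min(local)
        lowered = [v - delta for v in local]
        assert sleep_criterion(lowered, stats, params) is True


class TestStreaming:
    def test_warmup_gate_blocks_early_decisions(self):
        trace = make_trace([0.0] * 50)
        decisions = detect_stream(trace, DetectorParams(warmup_frames=30))
        asleep = [d.asleep for d in decisions]
        assert not any(asleep[:29])
        # all-zero trace: criterion holds by equality once eligible
        assert all(asleep[29:])

    def test_wake_then_sleep_trace_decisions(self, wake_sleep_trace):
        """20 active frames then 5 silent ones, warm-up 10.

        The silent tail is called asleep at the final frame (window of five
        zeros).  Mixed windows (frames 20-23) are not.  The leading constant
        segment satisfies both inclusive bounds by equality from the moment
        warm-up ends -- the documented degeneracy, asserted as such.
        """
        params = DetectorParams(warmup_frames=10)
        asleep = [d.asleep for d in detect_stream(wake_sleep_trace, params)]
        assert asleep[24] is True
        assert asleep[20:24] == [False] * 4
        assert all(asleep[9:20])  # constant-segment equality pathology
        assert not any(asleep[:9])

    def test_refractory_suppresses_after_stimulus(self):
        params = DetectorParams(warmup_frames=5)
        trace = make_trace([0.0] * 40)
        state = init_detector(params)
        asleep = []
        for sample in trace:
            if sample.t == 20:
                notify_stimulus(state)
            _, d = step_detector(state, sample)
            asleep.append(d.asleep)
        assert asleep[19] is True
        assert asleep[20:25] == [False] * 5  # refractory = window_w frames
        assert asleep[25] is True

    def test_out_of_order_sample_rejected(self):
        state = init_detector(DetectorParams())
        step_detector(state, ActivitySample(t=0, time_s=0.0, value=1.0))
        with pytest.raises(SequencingError):
            step_detector(state, ActivitySample(t=0, time_s=0.0, value=1.0))

    def test_asleep_implies_both_thresholds_held(self, rng):
        values = np.abs(rng.normal(50, 30, 400))
        values[200:260] = rng.uniform(0, 0.01, 60)
        decisions = detect_stream(make_trace(values), DetectorParams())
        hits = [d for d in decisions if d.asleep]
        assert hits  # the quiet stretch is detected
        for d in hits:
            assert d.local_std <= d.thr_std and d.local_mean <= d.thr_mean


class TestBatchOracle:
    def test_short_trace_rejected(self):
        with pytest.raises(InsufficientInputError):
            batch_detect(make_trace([1.0, 2.0]))

    def test_all_zero_trace_asleep_from_first_eligible_frame(self):
        decisions = batch_detect(make_trace([0.0] * 30),
                                 DetectorParams(warmup_frames=5))
        asleep = [d.asleep for d in decisions]
        assert asleep[:4] == [False] * 4 and all(asleep[4:])

    def test_strictly_increasing_trace_never_asleep(self):
        decisions = batch_detect(make_trace(np.arange(1.0, 501.0)),
                                 DetectorParams(warmup_frames=10))
        assert not any(d.asleep for d in decisions)

    @given(st.integers(0, 2**31 - 1))
    def test_streaming_equals_batch_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        values = np.abs(rng.normal(50, 40, 300))
        values[rng.integers(50, 250) :][:30] *= rng.uniform(0, 0.05)
        trace = make_trace(values)
        params = DetectorParams(warmup_frames=20)
        stream = [d.asleep for d in detect_stream(trace, params)]
        batch = [d.asleep for d in batch_detect(trace, params)]
        assert stream == batch

    def test_streaming_equals_batch_with_stimuli(self, rng):
        values = np.abs(rng.normal(10, 8, 200))
        trace = make_trace(values)
        params = DetectorParams(warmup_frames=10)
        stim = [40, 90, 91, 150]
        stream = [d.asleep for d in detect_stream(trace, params, stimulus_frames=stim)]
        batch = [d.asleep for d in batch_detect(trace, params, stimulus_frames=stim)]
        assert stream == batch

    def test_decision_frame_columns(self):
        decisions = batch_detect(make_trace([1.0] * 10), DetectorParams(warmup_frames=5))
        df = decisions_to_frame(decisions)
        assert list(df.columns) == [
            "frame_index", "time_s", "imsub", "local_mean", "local_std",
            "thr_std", "thr_mean", "asleep",
        ]
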