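"""Real-time sleep detection with a dual dynamic threshold.

The detector watches the frame-subtraction activity stream and declares
sleep when, over a short local window (default five frames), the activity
is both *stable* and *low* relative to the whole recording so far:

    std(local)  <=  std(global) / k_std
    mean(local) <=  mean(global) - (mean(global) - min(global)) / k_mean

with the global statistics accumulated from the very first activity value.
Because both bounds are fractions of running statistics rather than fixed
constants, the criterion transfers across strains, magnifications and
illumination levels without re-tuning.  Defaults instantiate the reference
operating point for wild-type worms: window of five frames, k_std = 40, k_mean = 1.5.

Both comparisons are inclusive.  A consequence worth knowing: on a
perfectly constant trace the criterion holds by equality (std 0 <= 0 and
mean c <= c).  This degenerate behavior is inherent to the criterion and is
kept as-is; the warm-up gate exists partly because early global statistics
are similarly degenerate.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .activity import ActivitySample, ActivityTrace
from .errors import (
    ContractError,
    InsufficientInputError,
    ParameterError,
    SequencingError,
)

__all__ = [
    "DetectorParams",
    "GlobalStats",
    "DetectorState",
    "Decision",
    "init_detector",
    "update_global_stats",
    "sleep_criterion",
    "mean_threshold",
    "mean_threshold_subtractive",
    "step_detector",
    "notify_stimulus",
    "batch_detect",
    "detect_stream",
    "decisions_to_frame",
]


@dataclass(frozen=True)
class DetectorParams:
    """Operating point of the dual dynamic threshold.

    window_w
        Length of the local window, in frames (reference value for wild-type worms: 5).
    k_std
        Divisor of the global standard deviation (reference value: 40).
    k_mean
        Divisor in the mean bound (reference value: 1.5).  Must exceed 1;
        at exactly 1 the rewritten bound collapses to min(global) with a
        vanishing mean term.
    warmup_frames
        Number of activity values that must accumulate before a sleep call
        is permitted (default 120 frames = 2 min at the 1 s default frame
        interval).  Early global statistics are too degenerate to threshold
        against.
    refractory_frames
        Frames after a mechanical stimulus during which detection is
        suppressed so the local window refills with post-stimulus values;
        defaults to window_w.
    """

    window_w: int = 5
    k_std: float = 40.0
    k_mean: float = 1.5
    warmup_frames: int = 120
    refractory_frames: int | None = None

    def __post_init__(self):
        problems = []
        if self.window_w < 2:
            problems.append(f"window_w must be >= 2 (got {self.window_w})")
        if not self.k_std > 0:
            problems.append(f"k_std must be > 0 (got {self.k_std})")
        if not self.k_mean > 1:
            problems.append(
                f"k_mean must be > 1 so the (k_mean - 1) coefficient stays "
                f"positive (got {self.k_mean})"
            )
        if self.warmup_frames < self.window_w:
            problems.append(
                f"warmup_frames must be >= window_w (got {self.warmup_frames} "
                f"< {self.window_w})"
            )
        if self.refractory_frames is None:
            object.__setattr__(self, "refractory_frames", self.window_w)
        elif self.refractory_frames < 0:
            problems.append("refractory_frames must be >= 0")
        if problems:
            raise ParameterError("; ".join(problems))


@dataclass
class GlobalStats:
    """Running mean / population std / min over all values seen so far.

    Uses Welford's online recurrence for the variance so long recordings do
    not lose precision to catastrophic cancellation.
    """

    n: int = 0
    mean: float = 0.0
    m2: float = 0.0
    min: float = math.inf

    @property
    def std(self) -> float:
        """Population standard deviation (divide by n)."""
        if self.n == 0:
            return 0.0
        return math.sqrt(max(self.m2 / self.n, 0.0))

    def push(self, value: float) -> None:
        value = float(value)
        if value < 0:
            raise ValueError(f"activity values are non-negative, got {value}")
        self.n += 1
        delta = value - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (value - self.mean)
        if value < self.min:
            self.min = value

    def copy(self) -> "GlobalStats":
        return GlobalStats(n=self.n, mean=self.mean, m2=self.m2, min=self.min)


def update_global_stats(stats: GlobalStats, value: float) -> GlobalStats:
    """Functional form of :meth:`GlobalStats.push` (returns a new object)."""
    out = stats.copy()
    out.push(value)
    return out


@dataclass(frozen=True)
class Decision:
    """Outcome of one detector step.

    ``criterion_met`` is the raw dual-threshold evaluation; ``asleep`` is
    the gated decision actually acted upon (false during warm-up, while the
    window is unfilled, and within the post-stimulus refractory period).
    """

    t: int
    time_s: float
    value: float
    asleep: bool
    criterion_met: bool
    local_mean: float = math.nan
    local_std: float = math.nan
    thr_std: float = math.nan
    thr_mean: float = math.nan


def mean_threshold(stats: GlobalStats, k_mean: float) -> float:
    """Rewritten mean bound: ((k_mean - 1) * mean + min) / k_mean."""
    return ((k_mean - 1.0) * stats.mean + stats.min) / k_mean


def mean_threshold_subtractive(stats: GlobalStats, k_mean: float) -> float:
    """Original mean bound: mean - (mean - min) / k_mean.

    Algebraically identical to :func:`mean_threshold`; kept as a separate
    code path so the identity can be cross-checked.
    """
    return stats.mean - (stats.mean - stats.min) / k_mean


def sleep_criterion(
    local: Sequence[float],
    stats: GlobalStats,
    params: DetectorParams,
) -> bool:
    """Evaluate the dual dynamic threshold on one local window.

    Both comparisons are inclusive (<=).  Requires a full window and at
    least window_w global values.
    """
    local = np.asarray(local, dtype=float)
    if local.shape != (params.window_w,):
        raise ContractError(
            f"local window must hold exactly {params.window_w} values, "
            f"got {local.shape}"
        )
    if stats.n < params.window_w:
        raise ContractError(
            f"global stats cover {stats.n} values; need >= {params.window_w}"
        )
    local_std = float(np.sqrt(np.mean((local - local.mean()) ** 2)))
    local_mean = float(local.mean())
    return (local_std <= stats.std / params.k_std) and (
        local_mean <= mean_threshold(stats, params.k_mean)
    )


@dataclass
class DetectorState:
    """Mutable state of the streaming detector."""

    params: DetectorParams
    stats: GlobalStats = field(default_factory=GlobalStats)
    recent: deque = field(default=None)  # type: ignore[assignment]
    frames_since_stimulus: int | None = None
    last_t: int | None = None

    def __post_init__(self):
        if self.recent is None:
            self.recent = deque(maxlen=self.params.window_w)

    def copy(self) -> "DetectorState":
        out = DetectorState(params=self.params, stats=self.stats.copy(),
                            frames_since_stimulus=self.frames_since_stimulus,
                            last_t=self.last_t)
        out.recent = deque(self.recent, maxlen=self.params.window_w)
        return out


def init_detector(params: DetectorParams | None = None) -> DetectorState:
    """Fresh detector state; raises ParameterError for invalid params."""
    return DetectorState(params=params if params is not None else DetectorParams())


def notify_stimulus(state: DetectorState) -> None:
    """Mark a mechanical stimulus; suppresses detection for the refractory."""
    state.frames_since_stimulus = 0


def step_detector(
    state: DetectorState, sample: ActivitySample
) -> tuple[DetectorState, Decision]:
    """Consume one activity sample and emit a decision.

    Mutates ``state`` in place and returns it alongside the decision.
    Samples must arrive with strictly increasing frame indices.
    """
    if state.last_t is not None and sample.t <= state.last_t:
        raise SequencingError(
            f"sample t={sample.t} arrived after t={state.last_t}"
        )
    state.last_t = sample.t
    state.stats.push(sample.value)
    state.recent.append(float(sample.value))
    if state.frames_since_stimulus is not None:
        state.frames_since_stimulus += 1

    p = state.params
    window_full = len(state.recent) == p.window_w
    if window_full:
        local = np.asarray(state.recent, dtype=float)
        local_mean = float(local.mean())
        local_std = float(np.sqrt(np.mean((local - local_mean) ** 2)))
        thr_std = state.stats.std / p.k_std
        thr_mean = mean_threshold(state.stats, p.k_mean)
        criterion = (local_std <= thr_std) and (local_mean <= thr_mean)
    else:
        local_mean = local_std = thr_std = thr_mean = math.nan
        criterion = False

    in_refractory = (
        state.frames_since_stimulus is not None
        and state.frames_since_stimulus <= p.refractory_frames
    )
    asleep = (
        criterion
        and window_full
        and state.stats.n >= p.warmup_frames
        and not in_refractory
    )
    decision = Decision(
        t=sample.t, time_s=sample.time_s, value=sample.value,
        asleep=asleep, criterion_met=criterion,
        local_mean=local_mean, local_std=local_std,
        thr_std=thr_std, thr_mean=thr_mean,
    )
    return state, decision


def detect_stream(
    trace: ActivityTrace,
    params: DetectorParams | None = None,
    stimulus_frames: Iterable[int] = (),
) -> list[Decision]:
    """Replay a recorded trace through the streaming detector.

    ``stimulus_frames`` lists sample indices at which a stimulus was
    delivered; the refractory gate is applied after each.
    """
    state = init_detector(params)
    stim = set(stimulus_frames)
    out = []
    for sample in trace:
        if sample.t in stim:
            notify_stimulus(state)
        _, decision = step_detector(state, sample)
        out.append(decision)
    return out


def batch_detect(
    trace: ActivityTrace,
    params: DetectorParams | None = None,
    stimulus_frames: Iterable[int] = (),
) -> list[Decision]:
    """Offline detector: recompute global statistics from scratch per frame.

    For every t the global mean/std/min are evaluated by batch formulas
    over samples 0..t (prefix sums), independent of the streaming
    recurrence, and the same dual threshold is applied.  Produces the same
    asleep sequence as the streaming path; serves as its oracle in tests.
    """
    params = params if params is not None else DetectorParams()
    v = np.asarray(trace.values, dtype=float)
    n = len(v)
    if n < params.window_w:
        raise InsufficientInputError(
            f"trace has {n} samples; need >= window_w = {params.window_w}"
        )
    idx = np.arange(1, n + 1, dtype=float)
    g_mean = np.cumsum(v) / idx
    g_var = np.cumsum(v * v) / idx - g_mean**2
    g_std = np.sqrt(np.clip(g_var, 0.0, None))
    g_min = np.minimum.accumulate(v)

    w = params.window_w
    windows = np.lib.stride_tricks.sliding_window_view(v, w)
    l_mean = windows.mean(axis=1)
    l_std = np.sqrt(np.mean((windows - l_mean[:, None]) ** 2, axis=1))

    stim = np.asarray(sorted(set(stimulus_frames)), dtype=int)

    decisions = []
    for t in range(n):
        window_full = t >= w - 1
        if window_full:
            lm, ls = float(l_mean[t - w + 1]), float(l_std[t - w + 1])
            thr_s = float(g_std[t] / params.k_std)
            thr_m = float(
                ((params.k_mean - 1.0) * g_mean[t] + g_min[t]) / params.k_mean
            )
            criterion = (ls <= thr_s) and (lm <= thr_m)
        else:
            lm = ls = thr_s = thr_m = math.nan
            criterion = False
        if stim.size:
            prior = stim[stim <= t]
            in_refractory = prior.size > 0 and (t - prior.max()) < params.refractory_frames
        else:
            in_refractory = False
        asleep = (
            criterion and window_full and (t + 1) >= params.warmup_frames
            and not in_refractory
        )
        decisions.append(
            Decision(t=t, time_s=float(trace.times_s[t]), value=float(v[t]),
                     asleep=asleep, criterion_met=criterion,
                     local_mean=lm, local_std=ls, thr_std=thr_s, thr_mean=thr_m)
        )
    return decisions


def decisions_to_frame(decisions: Sequence[Decision]) -> pd.DataFrame:
    """Decisions as a DataFrame with the documented CSV column layout."""
    return pd.DataFrame(
        {
            "frame_index": [d.t for d in decisions],
            "time_s": [d.time_s for d in decisions],
            "imsub": [d.value for d in decisions],
            "local_mean": [d.local_mean for d in decisions],
            "local_std": [d.local_std for d in decisions],
            "thr_std": [d.thr_std for d in decisions],
            "thr_mean": [d.thr_mean for d in decisions],
            "asleep": [d.asleep for d in decisions],
        }
    )
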