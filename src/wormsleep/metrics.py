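"""Behavioral quantification and detector evaluation.

Definitions follow the behavioral conventions of the lethargus-sleep
literature: sleep bouts are maximal runs of frames with no detectable nose
movement; the lethargus interval is the (longest) period without
peristaltic pharyngeal pumping; detector evaluation asks whether a sleep
call fell inside lethargus, optionally granting a tolerance window (default
5 min) before the non-pumping start, and reports the delay of the first
in-lethargus call.  All intervals are half-open ``[start_s, end_s)`` in
seconds with 0-based frame indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .detector import Decision
from .errors import (
    ContractError,
    DegenerateInputError,
    InsufficientInputError,
    LethargusNotFound,
)

__all__ = [
    "Interval",
    "DetectionEvaluation",
    "nose_speed",
    "sleep_bouts_from_speed",
    "lethargus_interval",
    "sleep_summary",
    "evaluate_detection",
    "rank_correlation",
    "event_aligned_mean",
]


@dataclass(frozen=True)
class Interval:
    """Half-open time interval [start_s, end_s) in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError(
                f"interval start must precede end: [{self.start_s}, {self.end_s})"
            )

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s

    def intersection_length(self, other: "Interval") -> float:
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))


@dataclass(frozen=True)
class DetectionEvaluation:
    """Outcome of comparing detector calls against the lethargus interval."""

    detected_in_lethargus: bool
    detected_with_tolerance: bool
    detection_delay_s: float | None


def nose_speed(positions_um: np.ndarray, frame_interval_s: float) -> np.ndarray:
    """Per-frame nose speed (um/s): Euclidean step / frame interval.

    ``positions_um`` is (n, 2); the result has length n - 1, speed k
    covering the step from frame k to k + 1.
    """
    pos = np.asarray(positions_um, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError(f"positions must be (n, 2), got {pos.shape}")
    if len(pos) < 2:
        raise InsufficientInputError("need at least 2 positions")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return steps / float(frame_interval_s)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True-runs of a boolean array as half-open index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def sleep_bouts_from_speed(
    speeds: np.ndarray,
    epsilon_um_s: float = 0.5,
    min_bout_frames: int = 1,
    frame_interval_s: float = 1.0,
) -> list[Interval]:
    """Sleep bouts: maximal runs of frames with speed <= epsilon.

    The default epsilon of 0.5 um/s is a localization-noise floor at
    ~1 um/pixel and 1 s frames ("no detectable movement"); runs shorter
    than ``min_bout_frames`` are dropped.  Frame runs [i, j) map to
    [i * dt, j * dt) seconds.
    """
    if epsilon_um_s < 0:
        raise ValueError("epsilon_um_s must be >= 0")
    speeds = np.asarray(speeds, dtype=float)
    dt = float(frame_interval_s)
    return [
        Interval(i * dt, j * dt)
        for i, j in _runs(speeds <= epsilon_um_s)
        if (j - i) >= min_bout_frames
    ]


def lethargus_interval(
    pumping: np.ndarray,
    frame_interval_s: float = 1.0,
    gap_bridge_frames: int = 0,
) -> Interval:
    """The longest maximal non-pumping run as a half-open interval in seconds.

    ``gap_bridge_frames`` > 0 merges non-pumping runs separated by at most
    that many pumping frames before taking the longest (robust to isolated
    pump-miss frames).  Raises LethargusNotFound if the worm always pumps.
    """
    pumping = np.asarray(pumping, dtype=bool)
    runs = _runs(~pumping)
    if not runs:
        raise LethargusNotFound("no non-pumping frames in the recording")
    if gap_bridge_frames > 0:
        merged = [list(runs[0])]
        for i, j in runs[1:]:
            if i - merged[-1][1] <= gap_bridge_frames:
                merged[-1][1] = j
            else:
                merged.append([i, j])
        runs = [tuple(r) for r in merged]
    i, j = max(runs, key=lambda r: r[1] - r[0])
    dt = float(frame_interval_s)
    return Interval(i * dt, j * dt)


def sleep_summary(bouts: Sequence[Interval], lethargus: Interval) -> dict:
    """Total sleep, sleep fraction and bout count within lethargus.

    Bout/lethargus intersections are what counts: a bout half inside the
    interval contributes only its inside half; bouts entirely outside
    contribute nothing (and are not counted).
    """
    overlaps = [b.intersection_length(lethargus) for b in bouts]
    total = float(sum(overlaps))
    count = int(sum(1 for o in overlaps if o > 0))
    return {
        "total_sleep_s": total,
        "sleep_fraction": total / lethargus.length_s,
        "bout_count": count,
    }


def evaluate_detection(
    decisions: Sequence[Decision],
    lethargus: Interval,
    tolerance_s: float = 300.0,
) -> DetectionEvaluation:
    """Did the detector call sleep during (or just before) lethargus?

    ``detected_in_lethargus``: some asleep call falls in [start, end).
    ``detected_with_tolerance``: additionally accepts calls in
    [start - tolerance, start) — the 5-min default mirrors the tolerance
    used when scoring detections against the non-pumping period.
    ``detection_delay_s``: first asleep call at/after lethargus start minus
    the start (None if there is none).
    """
    if not decisions:
        raise ContractError("no decisions supplied")
    times = np.asarray([d.time_s for d in decisions], dtype=float)
    step = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    if times[0] > lethargus.start_s or times[-1] < lethargus.end_s - step:
        raise ContractError(
            f"decisions [{times[0]}, {times[-1]}] do not cover lethargus "
            f"[{lethargus.start_s}, {lethargus.end_s})"
        )
    asleep_times = times[np.asarray([d.asleep for d in decisions], dtype=bool)]
    in_leth = bool(
        np.any((asleep_times >= lethargus.start_s) & (asleep_times < lethargus.end_s))
    )
    in_tol = in_leth or bool(
        np.any(
            (asleep_times >= lethargus.start_s - tolerance_s)
            & (asleep_times < lethargus.start_s)
        )
    )
    after = asleep_times[asleep_times >= lethargus.start_s]
    delay = float(after.min() - lethargus.start_s) if after.size else None
    return DetectionEvaluation(
        detected_in_lethargus=in_leth,
        detected_with_tolerance=in_tol,
        detection_delay_s=delay,
    )


def rank_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 3:
        raise InsufficientInputError("need 1-D sequences of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise DegenerateInputError("constant input has no rank ordering")
    rho = sps.spearmanr(a, b).statistic
    return float(rho)


def event_aligned_mean(
    traces: Sequence[np.ndarray],
    event_indices: Sequence[int],
    window_before: int,
    window_after: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average traces aligned to a per-trace event frame.

    Returns (offsets, mean, sem): offsets run from -window_before to
    +window_after (length window_before + window_after + 1); mean and
    s.e.m. are computed across traces at each aligned offset.  Traces whose
    window overflows the trace are excluded with a warning rather than
    silently truncated.
    """
    if len(traces) != len(event_indices):
        raise ValueError("one event index per trace required")
    rows = []
    for k, (trace, ev) in enumerate(zip(traces, event_indices)):
        trace = np.asarray(trace, dtype=float)
        lo, hi = ev - window_before, ev + window_after + 1
        if lo < 0 or hi > len(trace):
            warnings.warn(
                f"trace {k}: window [{lo}, {hi}) overflows length {len(trace)}; "
                "excluded from the aligned average",
                stacklevel=2,
            )
            continue
        rows.append(trace[lo:hi])
    if not rows:
        raise InsufficientInputError("no trace admits the requested window")
    stack = np.vstack(rows)
    offsets = np.arange(-window_before, window_after + 1)
    mean = stack.mean(axis=0)
    if len(stack) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(stack))
    else:
        sem = np.zeros_like(mean)
    return offsets, mean, sem
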