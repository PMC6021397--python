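"""Frame-subtraction activity measure.

Motion of a worm confined to a microchamber is quantified without any
segmentation or tracking: consecutive frames are subtracted pixelwise, the
absolute differences are summed over the whole frame, and the resulting
scalar per frame pair (``imsub``) serves as the activity signal that the
sleep detector thresholds.  A perfectly still worm under noise-free imaging
yields exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientInputError, ShapeMismatchError

__all__ = [
    "FrameImage",
    "DifferenceImage",
    "ActivitySample",
    "ActivityTrace",
    "difference_image",
    "activity_value",
    "activity_trace",
]


@dataclass(frozen=True)
class FrameImage:
    """One grayscale frame of the chamber.

    Parameters
    ----------
    pixels
        2-D non-negative intensity grid (arbitrary intensity units).  Any
        numeric dtype is accepted; 8/16-bit camera data is handled without
        unsigned wrap-around because differences are computed in float64.
    timestamp
        Seconds from recording start, or ``None`` if the source carries no
        timing information (it is then synthesized from the frame interval).
    """

    pixels: np.ndarray
    timestamp: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ShapeMismatchError(
                f"frame must be a 2-D grayscale grid, got shape {px.shape}"
            )
        if px.size == 0:
            raise ShapeMismatchError("frame must have at least one pixel")
        if np.any(px < 0):
            raise ValueError("frame intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class DifferenceImage:
    """Pixelwise absolute difference of two frames; all entries >= 0."""

    pixels: np.ndarray


@dataclass(frozen=True)
class ActivitySample:
    """One activity value, attributed to the earlier frame of the pair."""

    t: int
    time_s: float
    value: float


@dataclass
class ActivityTrace:
    """Time series of frame-subtraction values, one per consecutive pair."""

    values: np.ndarray
    frame_interval_s: float
    times_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("activity values must form a 1-D series")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")
        if self.times_s is None:
            self.times_s = np.arange(len(self.values)) * self.frame_interval_s
        else:
            self.times_s = np.asarray(self.times_s, dtype=float)
            if self.times_s.shape != self.values.shape:
                raise ShapeMismatchError("times and values must align")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, k: int) -> ActivitySample:
        return ActivitySample(t=int(k), time_s=float(self.times_s[k]),
                              value=float(self.values[k]))

    def __iter__(self) -> Iterator[ActivitySample]:
        for k in range(len(self)):
            yield self[k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self.values), dtype=int),
                "time_s": self.times_s,
                "imsub": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval_s: float | None = None) -> "ActivityTrace":
        df = pd.read_csv(path)
        for col in ("frame_index", "time_s", "imsub"):
            if col not in df.columns:
                raise ValueError(f"activity CSV missing column {col!r}")
        times = df["time_s"].to_numpy(float)
        if frame_interval_s is None:
            frame_interval_s = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        return cls(values=df["imsub"].to_numpy(float),
                   frame_interval_s=frame_interval_s, times_s=times)


def _check_same_shape(a: FrameImage, b: FrameImage) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ShapeMismatchError(
            f"frame dimensions differ: {a.pixels.shape} vs {b.pixels.shape}"
        )


def difference_image(a: FrameImage, b: FrameImage) -> DifferenceImage:
    """Pixelwise ``|b - a|`` in float64 (safe for unsigned integer inputs)."""
    _check_same_shape(a, b)
    diff = np.abs(b.pixels.astype(np.float64) - a.pixels.astype(np.float64))
    return DifferenceImage(pixels=diff)


def activity_value(a: FrameImage, b: FrameImage, noise_floor: float = 0.0) -> float:
    """Sum of absolute pixel differences between two frames.

    ``noise_floor`` (default 0 = off) subtracts a constant from every
    difference pixel and clips at zero before summing, as a crude camera
    noise clamp; the canonical measure sums raw differences.
    """
    diff = difference_image(a, b).pixels
    if noise_floor > 0:
        diff = np.clip(diff - noise_floor, 0.0, None)
    return float(diff.sum())


def activity_trace(
    frames: Sequence[FrameImage],
    frame_interval_s: float,
    noise_floor: float = 0.0,
) -> ActivityTrace:
    """Activity series over consecutive frame pairs; length = n_frames - 1.

    Sample ``k`` holds the subtraction value of frames ``k`` and ``k + 1``
    and is timestamped at frame ``k`` (the earlier frame of the pair), using
    the frame's own timestamp when present.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise InsufficientInputError(
            f"need at least 2 frames to form a trace, got {len(frames)}"
        )
    shape = frames[0].pixels.shape
    for k, fr in enumerate(frames[1:], start=1):
        if fr.pixels.shape != shape:
            raise ShapeMismatchError(
                f"frame {k} has shape {fr.pixels.shape}, expected {shape}"
            )
    values = np.empty(len(frames) - 1)
    times = np.empty(len(frames) - 1)
    for k in range(len(frames) - 1):
        values[k] = activity_value(frames[k], frames[k + 1], noise_floor=noise_floor)
        ts = frames[k].timestamp
        times[k] = ts if ts is not None else k * frame_interval_s
    return ActivityTrace(values=values, frame_interval_s=frame_interval_s,
                         times_s=times)
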