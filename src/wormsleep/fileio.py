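"""File I/O and run configuration.

Frames come in as multi-page TIFF stacks or lexicographically ordered
single-image files (TIFF/PNG), strictly grayscale; RGB input is rejected
rather than silently converted.  The run configuration is one YAML mapping
mirroring the settings a rig operator would set: detector operating point,
tap protocol, behavior-generator parameters, chamber geometry, frame
interval (default 1.0 s; supported range 0.5-4.0 s) and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from . import __version__
from .activity import FrameImage
from .controller import ControllerConfig, ExtendedProtocol, TapProtocol
from .detector import DetectorParams
from .errors import ParameterError, ShapeMismatchError
from .synthetic import BehaviorParams, ChamberGeometry

__all__ = [
    "RoiSpec",
    "RunConfig",
    "read_frames",
    "load_config",
    "write_config",
    "write_provenance",
    "FRAME_INTERVAL_RANGE_S",
]

FRAME_INTERVAL_RANGE_S = (0.5, 4.0)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular crop in pixel coordinates, 0-based, half-open."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ParameterError(
                f"ROI must satisfy x0 < x1 and y0 < y1, got {self}"
            )
        if min(self.x0, self.y0) < 0:
            raise ParameterError("ROI coordinates must be non-negative")

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        h, w = pixels.shape
        if self.x1 > w or self.y1 > h:
            raise ShapeMismatchError(
                f"ROI {self} exceeds frame bounds {h}x{w}"
            )
        return pixels[self.y0 : self.y1, self.x0 : self.x1]


def _as_grayscale(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{source}: RGB(A) input is not supported; supply grayscale frames"
        )
    if arr.ndim != 2:
        raise ShapeMismatchError(f"{source}: expected a 2-D frame, got {arr.shape}")
    return arr


def read_frames(
    path,
    roi: RoiSpec | None = None,
    frame_interval_s: float = 1.0,
) -> list[FrameImage]:
    """Read an image sequence as FrameImage objects in acquisition order.

    ``path`` is either a TIFF file (pages in order) or a directory of
    single-frame TIFF/PNG files read in lexicographic name order.
    Timestamps are synthesized as k * frame_interval_s.
    """
    path = Path(path)
    arrays: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames in directory {path}")
        for p in files:
            arrays.append(_as_grayscale(np.asarray(iio.imread(p)), p.name))
    else:
        stack = tifffile.imread(path)
        stack = np.asarray(stack)
        if stack.ndim == 2:
            arrays = [_as_grayscale(stack, str(path))]
        elif stack.ndim == 3 and stack.shape[-1] in (3, 4):
            raise ValueError(f"{path}: RGB(A) input is not supported")
        elif stack.ndim == 3:
            arrays = [_as_grayscale(page, f"{path}[{i}]")
                      for i, page in enumerate(stack)]
        else:
            raise ShapeMismatchError(f"{path}: unsupported stack shape {stack.shape}")
    if not arrays:
        raise FileNotFoundError(f"empty stack: {path}")
    shape = arrays[0].shape
    for i, arr in enumerate(arrays):
        if arr.shape != shape:
            raise ShapeMismatchError(
                f"frame {i} has shape {arr.shape}, expected {shape}"
            )
    if roi is not None:
        arrays = [roi.crop(arr) for arr in arrays]
    return [
        FrameImage(pixels=arr.astype(np.float64), timestamp=k * frame_interval_s)
        for k, arr in enumerate(arrays)
    ]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    detector: DetectorParams = field(default_factory=DetectorParams)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    chamber: ChamberGeometry = field(default_factory=ChamberGeometry)
    frame_interval_s: float = 1.0
    duration_s: float = 1200.0
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        lo, hi = FRAME_INTERVAL_RANGE_S
        if not (lo <= self.frame_interval_s <= hi):
            raise ParameterError(
                f"frame_interval_s must lie in [{lo}, {hi}] s, "
                f"got {self.frame_interval_s}"
            )
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")


_SECTION_TYPES = {
    "detector": DetectorParams,
    "behavior": BehaviorParams,
    "chamber": ChamberGeometry,
}


def _build_dataclass(cls, mapping: dict, context: str):
    if not isinstance(mapping, dict):
        raise ParameterError(f"{context}: expected a mapping, got {type(mapping)}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ParameterError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**mapping)


def _controller_from_mapping(mapping: dict) -> ControllerConfig:
    mapping = dict(mapping)
    kwargs = {}
    if "tap_protocol" in mapping:
        kwargs["tap_protocol"] = _build_dataclass(
            TapProtocol, mapping.pop("tap_protocol"), "controller.tap_protocol"
        )
    if "extended" in mapping:
        kwargs["extended"] = _build_dataclass(
            ExtendedProtocol, mapping.pop("extended"), "controller.extended"
        )
    known = {f.name for f in dataclasses.fields(ControllerConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ParameterError(f"controller: unknown keys {sorted(unknown)}")
    return ControllerConfig(**mapping, **kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys take documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw = {} if raw is None else raw
    if not isinstance(raw, dict):
        raise ParameterError("config root must be a mapping")
    known_top = {"detector", "controller", "behavior", "chamber",
                 "frame_interval_s", "duration_s", "seed", "output_dir"}
    unknown = set(raw) - known_top
    if unknown:
        raise ParameterError(f"unknown top-level config keys {sorted(unknown)}")
    kwargs = {}
    for key, cls in _SECTION_TYPES.items():
        if key in raw:
            kwargs[key] = _build_dataclass(cls, raw[key], key)
    if "controller" in raw:
        kwargs["controller"] = _controller_from_mapping(raw["controller"])
    for key in ("frame_interval_s", "duration_s", "seed", "output_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig to YAML; load(write(cfg)) == cfg."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def write_provenance(cfg: RunConfig, path, extra: dict | None = None) -> None:
    """Machine-readable record sufficient to reproduce a run exactly."""
    record = {
        "wormsleep_version": __version__,
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
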