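"""Synthetic worm behavior and chamber-video generator.

Ground truth for every other module: a single L1-stage worm confined to a
190 x 190 um hydrogel microchamber, imaged at ~1 um/pixel.  Outside
lethargus the worm is awake, pumping, and its nose performs a bounded
random walk at ~16 um/s.  Inside lethargus pumping stops and behavior
alternates between motion bouts (reduced speed) and sleep bouts (nose
speed exactly zero), with exponentially distributed bout durations.  A tap
train delivered during a sleep bout wakes the worm into a motion bout with
the current response probability, which decays multiplicatively with each
answered train (habituation).

The worm is rendered as a bright anisotropic Gaussian blob aligned with
its heading on a dark background with optional Gaussian pixel noise
(clipped at zero).  The detection algorithm consumes only intensity
differences, so blob realism is deliberately minimal; see docs/methods.md
for what this does and does not emulate.

Timescales are compressed relative to a real recording (a real L1
lethargus lasts hours) so that a full wake - lethargus - wake experiment
fits in a short simulated run while preserving the structure the detector
and controller rely on: bout durations long relative to the five-frame
detection window, and a pre-lethargus wake span longer than the detector
warm-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .activity import ActivityTrace, FrameImage
from .errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .controller import StimulusSchedule

__all__ = [
    "ChamberGeometry",
    "BehaviorParams",
    "WormState",
    "BehaviorTrace",
    "simulate_step",
    "simulate_behavior",
    "render_frame",
    "SimulatedWorm",
    "standard_fixture",
]

WAKE = "wake"
MOTION_BOUT = "motion_bout"
SLEEP_BOUT = "sleep_bout"


@dataclass(frozen=True)
class ChamberGeometry:
    """Microchamber footprint; frames are side_um/resolution pixels square."""

    side_um: float = 190.0
    resolution_um_per_px: float = 1.0

    def __post_init__(self):
        if self.side_um <= 0 or self.resolution_um_per_px <= 0:
            raise ParameterError("chamber side and resolution must be positive")

    @property
    def n_px(self) -> int:
        return int(round(self.side_um / self.resolution_um_per_px))


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters of the synthetic worm.

    Speeds are mean nose speeds in um/s; bout durations are exponential
    with the given means (memoryless alternation is the simplest model
    consistent with bout-structured quiescence).  ``tap_response_prob_initial``
    is the per-tap probability that a tap wakes a sleeping worm; it decays
    by ``habituation_decay`` once per answered train.  ``noise_sigma`` is
    the Gaussian pixel-noise standard deviation in intensity units, small
    relative to the blob amplitude because whole-frame absolute-difference
    sums amplify per-pixel noise by the pixel count.
    """

    lethargus_start_s: float = 240.0
    lethargus_end_s: float = 720.0
    wake_speed_um_s: float = 16.0
    motion_speed_um_s: float = 8.0
    sleep_bout_mean_s: float = 30.0
    motion_bout_mean_s: float = 15.0
    tap_response_prob_initial: float = 1.0
    habituation_decay: float = 0.8
    noise_sigma: float = 0.2
    blob_amplitude: float = 150.0
    blob_sigma_long_um: float = 12.0
    blob_sigma_short_um: float = 5.0
    background: float = 10.0
    heading_diffusion_rad: float = 0.6

    def __post_init__(self):
        if not (0.0 <= self.tap_response_prob_initial <= 1.0):
            raise ParameterError("tap_response_prob_initial must be in [0, 1]")
        if not (0.0 <= self.habituation_decay <= 1.0):
            raise ParameterError("habituation_decay must be in [0, 1]")
        if self.lethargus_end_s <= self.lethargus_start_s:
            raise ParameterError("lethargus interval must have positive length")
        for name in ("wake_speed_um_s", "motion_speed_um_s", "sleep_bout_mean_s",
                     "motion_bout_mean_s", "blob_amplitude", "blob_sigma_long_um",
                     "blob_sigma_short_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.noise_sigma < 0 or self.background < 0:
            raise ParameterError("noise_sigma and background must be >= 0")


@dataclass
class WormState:
    """Instantaneous state of the simulated worm."""

    nose_xy_um: np.ndarray
    heading_rad: float
    behavioral_state: str
    pumping: bool
    response_prob: float
    bout_time_left_s: float = 0.0

    def copy(self) -> "WormState":
        return WormState(
            nose_xy_um=self.nose_xy_um.copy(), heading_rad=self.heading_rad,
            behavioral_state=self.behavioral_state, pumping=self.pumping,
            response_prob=self.response_prob,
            bout_time_left_s=self.bout_time_left_s,
        )


@dataclass
class BehaviorTrace:
    """Per-frame ground truth of one simulated recording."""

    time_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    state: np.ndarray          # strings in {wake, motion_bout, sleep_bout}
    pumping: np.ndarray        # bool
    tapped: np.ndarray         # bool: a tap landed in the frame's interval
    frame_interval_s: float
    params: BehaviorParams

    def __len__(self) -> int:
        return len(self.time_s)

    def lethargus_mask(self) -> np.ndarray:
        return ~self.pumping

    def sleep_fraction_in_lethargus(self) -> float:
        """Fraction of lethargus frames labeled sleep_bout (ground truth)."""
        mask = self.lethargus_mask()
        if not mask.any():
            return float("nan")
        return float(np.mean(self.state[mask] == SLEEP_BOUT))

    def nose_positions_um(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self), dtype=int),
                "time_s": self.time_s,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "state": self.state,
                "pumping": self.pumping.astype(int),
                "tapped": self.tapped.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _draw_bout(state_name: str, params: BehaviorParams, rng: np.random.Generator) -> float:
    mean = (params.sleep_bout_mean_s if state_name == SLEEP_BOUT
            else params.motion_bout_mean_s)
    return float(rng.exponential(mean))


def _move(state: WormState, mean_speed: float, dt: float,
          params: BehaviorParams, chamber: ChamberGeometry,
          rng: np.random.Generator) -> None:
    """Bounded random walk: Rayleigh per-frame speed, diffusing heading."""
    # Rayleigh with the requested mean: scale = mean / sqrt(pi/2)
    speed = rng.rayleigh(mean_speed / np.sqrt(np.pi / 2.0))
    state.heading_rad += rng.normal(0.0, params.heading_diffusion_rad)
    step = speed * dt * np.array(
        [np.cos(state.heading_rad), np.sin(state.heading_rad)]
    )
    pos = state.nose_xy_um + step
    side = chamber.side_um
    # reflect at the chamber walls
    for ax in (0, 1):
        while pos[ax] < 0 or pos[ax] > side:
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
            else:
                pos[ax] = 2 * side - pos[ax]
    state.nose_xy_um = pos


def simulate_step(
    state: WormState,
    taps_now: bool,
    params: BehaviorParams,
    rng: np.random.Generator,
    t_s: float,
    dt: float,
    chamber: ChamberGeometry | None = None,
) -> WormState:
    """Advance the worm by one frame interval; returns the new state.

    ``t_s`` is the time of the frame being produced.  Sleep-bout frames
    have exactly zero nose displacement; a tap during a sleep bout wakes
    the worm into a motion bout with probability ``response_prob`` and, if
    answered, decays the response probability once.
    """
    chamber = chamber if chamber is not None else ChamberGeometry()
    new = state.copy()
    in_lethargus = params.lethargus_start_s <= t_s < params.lethargus_end_s

    if not in_lethargus:
        new.behavioral_state = WAKE
        new.pumping = True
        new.bout_time_left_s = 0.0
        _move(new, params.wake_speed_um_s, dt, params, chamber, rng)
        return new

    new.pumping = False
    if new.behavioral_state == WAKE:  # entering lethargus
        new.behavioral_state = MOTION_BOUT
        new.bout_time_left_s = _draw_bout(MOTION_BOUT, params, rng)

    if taps_now and new.behavioral_state == SLEEP_BOUT:
        if rng.random() < new.response_prob:
            new.behavioral_state = MOTION_BOUT
            new.bout_time_left_s = _draw_bout(MOTION_BOUT, params, rng)
            new.response_prob *= params.habituation_decay

    new.bout_time_left_s -= dt
    if new.bout_time_left_s <= 0:
        nxt = MOTION_BOUT if new.behavioral_state == SLEEP_BOUT else SLEEP_BOUT
        new.behavioral_state = nxt
        new.bout_time_left_s = _draw_bout(nxt, params, rng)

    if new.behavioral_state == MOTION_BOUT:
        _move(new, params.motion_speed_um_s, dt, params, chamber, rng)
    # sleep bout: nose displacement exactly zero, heading frozen
    return new


def render_frame(
    state: WormState,
    chamber: ChamberGeometry,
    params: BehaviorParams,
    rng: np.random.Generator | None = None,
) -> FrameImage:
    """Render the worm as an anisotropic Gaussian blob plus pixel noise.

    Deterministic function of the state; noise (if noise_sigma > 0) is
    drawn from ``rng`` over the full frame and the result is clipped at
    zero.  The blob centroid sits at the nose position to sub-pixel
    accuracy via direct evaluation of the Gaussian on the pixel grid.
    """
    n = chamber.n_px
    res = chamber.resolution_um_per_px
    img = np.full((n, n), params.background, dtype=np.float64)

    cx, cy = state.nose_xy_um / res
    s_long = params.blob_sigma_long_um / res
    s_short = params.blob_sigma_short_um / res
    half = int(np.ceil(4 * s_long)) + 1
    x0, x1 = max(0, int(cx) - half), min(n, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(n, int(cy) + half + 1)
    if x1 > x0 and y1 > y0:
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        gx, gy = np.meshgrid(xs, ys)
        c, s = np.cos(state.heading_rad), np.sin(state.heading_rad)
        u = c * gx + s * gy        # along-body axis
        v = -s * gx + c * gy       # across-body axis
        blob = params.blob_amplitude * np.exp(
            -0.5 * ((u / s_long) ** 2 + (v / s_short) ** 2)
        )
        img[y0:y1, x0:x1] += blob

    if params.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)
        np.clip(img, 0.0, None, out=img)
    return FrameImage(pixels=img)


class SimulatedWorm:
    """Steppable single-worm simulator feeding the closed-loop controller.

    Each :meth:`step` advances the behavior by one frame interval, renders
    the new frame, and returns the frame-subtraction activity value between
    the previous and the new frame.  Behavior and pixel noise consume
    independent substreams of one seeded generator, so toggling rendering
    noise does not perturb the behavioral trajectory.
    """

    def __init__(
        self,
        params: BehaviorParams | None = None,
        chamber: ChamberGeometry | None = None,
        frame_interval_s: float = 1.0,
        seed: int = 0,
    ):
        self.params = params if params is not None else BehaviorParams()
        self.chamber = chamber if chamber is not None else ChamberGeometry()
        self.dt = float(frame_interval_s)
        root = np.random.default_rng(seed)
        self._behavior_rng, self._noise_rng = root.spawn(2)
        side = self.chamber.side_um
        self.state = WormState(
            nose_xy_um=np.array([side / 2.0, side / 2.0]),
            heading_rad=float(self._behavior_rng.uniform(0, 2 * np.pi)),
            behavioral_state=WAKE,
            pumping=True,
            response_prob=self.params.tap_response_prob_initial,
            bout_time_left_s=0.0,
        )
        self.frame_index = 0
        self._prev_frame = render_frame(self.state, self.chamber, self.params,
                                        self._noise_rng)
        self._records = [self._record(tapped=False)]

    def _record(self, tapped: bool) -> tuple:
        s = self.state
        return (self.frame_index * self.dt, s.nose_xy_um[0], s.nose_xy_um[1],
                s.behavioral_state, s.pumping, tapped)

    def step(self, taps_now: bool = False) -> float:
        """Advance one frame; returns activity between previous and new frame."""
        self.frame_index += 1
        t_s = self.frame_index * self.dt
        self.state = simulate_step(self.state, taps_now, self.params,
                                   self._behavior_rng, t_s, self.dt, self.chamber)
        frame = render_frame(self.state, self.chamber, self.params,
                             self._noise_rng)
        value = float(np.abs(frame.pixels - self._prev_frame.pixels).sum())
        self._prev_frame = frame
        self._records.append(self._record(tapped=taps_now))
        return value

    @property
    def response_prob(self) -> float:
        return self.state.response_prob

    def behavior_trace(self) -> BehaviorTrace:
        cols = list(zip(*self._records))
        return BehaviorTrace(
            time_s=np.asarray(cols[0], dtype=float),
            x_um=np.asarray(cols[1], dtype=float),
            y_um=np.asarray(cols[2], dtype=float),
            state=np.asarray(cols[3], dtype=object),
            pumping=np.asarray(cols[4], dtype=bool),
            tapped=np.asarray(cols[5], dtype=bool),
            frame_interval_s=self.dt,
            params=self.params,
        )


def simulate_behavior(
    params: BehaviorParams | None = None,
    duration_s: float = 1200.0,
    frame_interval_s: float = 1.0,
    seed: int = 0,
    schedule: Optional["StimulusSchedule"] = None,
    chamber: ChamberGeometry | None = None,
    collect_frames: bool = False,
) -> BehaviorTrace | tuple[BehaviorTrace, ActivityTrace]:
    """Run the worm open-loop for ``duration_s`` and return the ground truth.

    ``schedule`` optionally delivers scheduled tap trains (a tap landing in
    the interval (t_{k-1}, t_k] flags frame k).  With ``collect_frames``
    the rendered activity trace is returned as well.
    """
    params = params if params is not None else BehaviorParams()
    if duration_s < params.lethargus_end_s:
        raise ParameterError(
            "duration_s must cover the lethargus interval "
            f"({duration_s} < {params.lethargus_end_s})"
        )
    worm = SimulatedWorm(params=params, chamber=chamber,
                         frame_interval_s=frame_interval_s, seed=seed)
    n_frames = int(round(duration_s / frame_interval_s))
    tap_times: list[float] = []
    if schedule is not None:
        from .controller import plan_tap_train, TapProtocol
        for ev in schedule.events:
            tap_times.extend(
                plan_tap_train(ev.time_s,
                               TapProtocol(ev.taps_per_train, ev.inter_tap_interval_s),
                               frame_interval_s=frame_interval_s)
            )
    tap_times_arr = np.asarray(sorted(tap_times))
    values = np.empty(n_frames - 1)
    for k in range(1, n_frames):
        lo, hi = (k - 1) * frame_interval_s, k * frame_interval_s
        taps = bool(np.any((tap_times_arr > lo) & (tap_times_arr <= hi))) \
            if tap_times_arr.size else False
        values[k - 1] = worm.step(taps_now=taps)
    trace = worm.behavior_trace()
    if collect_frames:
        return trace, ActivityTrace(values=values, frame_interval_s=frame_interval_s)
    return trace


def standard_fixture(
    seed: int,
    noise_sigma: float | None = None,
    duration_s: float = 1200.0,
    frame_interval_s: float = 1.0,
) -> tuple[BehaviorTrace, ActivityTrace]:
    """The repo-standard open-loop recording: defaults, optional noise override.

    Returns the ground-truth behavior and the rendered activity trace of an
    unstimulated run long enough to span warm-up, lethargus and recovery.
    """
    params = BehaviorParams()
    if noise_sigma is not None:
        params = replace(params, noise_sigma=noise_sigma)
    return simulate_behavior(params=params, duration_s=duration_s,
                             frame_interval_s=frame_interval_s, seed=seed,
                             collect_frames=True)
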