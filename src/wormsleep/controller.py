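"""Closed-loop sleep deprivation and scheduled-stimulus control.

Protocol: watch the activity stream with the dynamic-threshold detector;
as soon as a sleep bout is detected, deliver a tap train (default 5 taps,
1 s apart).  Whenever the worm falls back asleep, stimulate again.  Once
the animal stops responding to a configurable number of consecutive
trains, switch to an extended, detection-independent stimulation protocol
(fixed-period trains) to probe the effect of sustained stimulation, then
stop.  A control mode replays a tap schedule from a text file irrespective
of behavior.

Tap times are staggered against frame exposures (each tap is shifted to
the midpoint between the two nearest frame times) so that a vibration
never blurs an acquisition, mirroring the hardware interlock of the real
rig.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import ActivitySample
from .detector import (
    Decision,
    DetectorParams,
    DetectorState,
    decisions_to_frame,
    init_detector,
    notify_stimulus,
    sleep_criterion,
    step_detector,
)
from .errors import ContractError, ParameterError, ScheduleParseError

__all__ = [
    "TapProtocol",
    "ExtendedProtocol",
    "ControllerConfig",
    "ScheduledTrain",
    "StimulusSchedule",
    "plan_tap_train",
    "load_stimulus_schedule",
    "assess_response",
    "run_closed_loop",
    "ExperimentLog",
]

PHASE_BASELINE = "baseline"
PHASE_CLOSED_LOOP = "closed_loop"
PHASE_EXTENDED = "extended"
PHASE_DONE = "done"


@dataclass(frozen=True)
class TapProtocol:
    """One mechanical stimulus train: 5 taps 1 s apart by default."""

    taps_per_train: int = 5
    inter_tap_interval_s: float = 1.0

    def __post_init__(self):
        if self.taps_per_train < 1:
            raise ParameterError("taps_per_train must be >= 1")
        if self.inter_tap_interval_s <= 0:
            raise ParameterError("inter_tap_interval_s must be > 0")


@dataclass(frozen=True)
class ExtendedProtocol:
    """Fixed-period stimulation once the worm stops responding."""

    train_period_s: float = 60.0
    duration_s: float = 1800.0

    def __post_init__(self):
        if self.train_period_s <= 0 or self.duration_s <= 0:
            raise ParameterError("extended-protocol periods must be > 0")


@dataclass(frozen=True)
class ControllerConfig:
    mode: str = "deprivation"  # or "control"
    tap_protocol: TapProtocol = field(default_factory=TapProtocol)
    response_window_frames: int = 10
    max_unresponsive_trains: int = 3
    extended: ExtendedProtocol = field(default_factory=ExtendedProtocol)

    def __post_init__(self):
        if self.mode not in ("deprivation", "control"):
            raise ParameterError(f"mode must be deprivation|control, got {self.mode!r}")
        if self.response_window_frames < 1:
            raise ParameterError("response_window_frames must be >= 1")
        if self.max_unresponsive_trains < 1:
            raise ParameterError("max_unresponsive_trains must be >= 1")


@dataclass(frozen=True)
class ScheduledTrain:
    time_s: float
    taps_per_train: int
    inter_tap_interval_s: float


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered tap trains for control mode; times strictly increasing."""

    events: tuple[ScheduledTrain, ...] = ()

    def __post_init__(self):
        times = [ev.time_s for ev in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("schedule times must be strictly increasing")


def plan_tap_train(
    trigger_time_s: float,
    protocol: TapProtocol | None = None,
    frame_interval_s: float | None = None,
) -> list[float]:
    """Tap times of one train starting at ``trigger_time_s``.

    Without ``frame_interval_s`` the raw (pre-stagger) times are returned:
    taps_per_train taps spaced inter_tap_interval_s apart.  With it, every
    tap is shifted to the midpoint between the two nearest frame times, so
    no tap coincides with an exposure.
    """
    if trigger_time_s < 0:
        raise ParameterError("trigger_time_s must be >= 0")
    protocol = protocol if protocol is not None else TapProtocol()
    raw = [trigger_time_s + i * protocol.inter_tap_interval_s
           for i in range(protocol.taps_per_train)]
    if frame_interval_s is None:
        return raw
    dt = float(frame_interval_s)
    return [(np.floor(t / dt) + 0.5) * dt for t in raw]


def load_stimulus_schedule(path) -> StimulusSchedule:
    """Parse a stimulus text file: ``time_s n_taps interval_s`` per line.

    Blank lines and ``#`` comments are ignored.  Malformed lines and
    non-increasing times raise ScheduleParseError with the line number.
    """
    events: list[ScheduledTrain] = []
    last_time = None
    with open(path) as fh:
        for line_no, raw_line in enumerate(fh, start=1):
            line = raw_line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ScheduleParseError(
                    f"expected 'time_s n_taps interval_s', got {line!r}", line_no
                )
            try:
                t = float(parts[0])
                n = int(parts[1])
                iv = float(parts[2])
            except ValueError as exc:
                raise ScheduleParseError(str(exc), line_no) from None
            if last_time is not None and t <= last_time:
                raise ScheduleParseError(
                    f"time {t} not greater than previous {last_time}", line_no
                )
            if n < 1 or iv <= 0:
                raise ScheduleParseError(
                    f"invalid train: n_taps={n}, interval={iv}", line_no
                )
            last_time = t
            events.append(ScheduledTrain(t, n, iv))
    return StimulusSchedule(events=tuple(events))


def assess_response(
    trace_after_train: Sequence[ActivitySample],
    state: DetectorState,
    cfg: ControllerConfig,
) -> bool:
    """Did the worm respond to a tap train?

    Replays the post-train samples through a copy of the detector state and
    declares the worm responsive iff the raw sleep criterion evaluates
    false for at least one frame of the response window (the refractory
    gate is deliberately ignored here: it would mask genuine quiescence).
    """
    samples = list(trace_after_train)
    if len(samples) < cfg.response_window_frames:
        raise ContractError(
            f"response window needs {cfg.response_window_frames} frames, "
            f"got {len(samples)}"
        )
    probe = state.copy()
    responsive = False
    for sample in samples[: cfg.response_window_frames]:
        probe.stats.push(sample.value)
        probe.recent.append(float(sample.value))
        if len(probe.recent) == probe.params.window_w:
            if not sleep_criterion(list(probe.recent), probe.stats, probe.params):
                responsive = True
    return responsive


@dataclass
class TrainRecord:
    train_id: int
    trigger_time_s: float
    tap_times_s: tuple[float, ...]
    phase: str
    responsive: bool | None = None  # None: not assessed (extended/control)


@dataclass
class ExperimentLog:
    """Full record of one closed-loop (or control) run."""

    decisions: list[Decision]
    phases: list[str]                  # one label per activity sample
    trains: list[TrainRecord]
    behavior: "object" = None          # BehaviorTrace when available
    frame_interval_s: float = 1.0
    config: ControllerConfig | None = None
    detector_params: DetectorParams | None = None

    @property
    def tap_times(self) -> list[float]:
        return [t for tr in self.trains for t in tr.tap_times_s]

    def to_frame(self) -> pd.DataFrame:
        df = decisions_to_frame(self.decisions)
        df["phase"] = self.phases
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def sidecar(self) -> dict:
        """JSON-serializable record of trains and phase boundaries."""
        phases = np.asarray(self.phases, dtype=object)
        boundaries = [
            {"phase": str(phases[i]), "start_time_s": float(self.decisions[i].time_s)}
            for i in range(len(phases))
            if i == 0 or phases[i] != phases[i - 1]
        ]
        return {
            "trains": [
                {
                    "train_id": tr.train_id,
                    "trigger_time_s": tr.trigger_time_s,
                    "tap_times_s": list(tr.tap_times_s),
                    "phase": tr.phase,
                    "responsive": tr.responsive,
                }
                for tr in self.trains
            ],
            "phase_boundaries": boundaries,
        }

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2)


def run_closed_loop(
    worm,
    detector_params: DetectorParams | None = None,
    cfg: ControllerConfig | None = None,
    duration_s: float = 1200.0,
    schedule: StimulusSchedule | None = None,
) -> ExperimentLog:
    """Run the full protocol against a steppable worm simulator.

    ``worm`` must expose ``step(taps_now: bool) -> float`` (activity value
    of the new frame pair) and a ``dt`` frame interval; `SimulatedWorm`
    satisfies this, as do scripted test doubles.  In deprivation mode the
    detector triggers tap trains; in control mode taps come only from
    ``schedule``.  The run is fully deterministic given the worm's seed and
    the configuration.
    """
    detector_params = detector_params if detector_params is not None else DetectorParams()
    cfg = cfg if cfg is not None else ControllerConfig()
    dt = float(getattr(worm, "dt", 1.0))
    n_frames = int(round(duration_s / dt))

    state = init_detector(detector_params)
    decisions: list[Decision] = []
    phases: list[str] = []
    trains: list[TrainRecord] = []

    pending_taps: list[float] = []       # scheduled, not yet delivered
    phase = PHASE_BASELINE
    unresponsive_count = 0
    extended_until: float | None = None
    next_extended_train: float | None = None
    # response assessment in flight: [criterion flags, last_tap_time, record]
    awaiting: list | None = None

    if cfg.mode == "control" and schedule is not None:
        for ev in schedule.events:
            proto = TapProtocol(ev.taps_per_train, ev.inter_tap_interval_s)
            taps = plan_tap_train(ev.time_s, proto, frame_interval_s=dt)
            trains.append(TrainRecord(train_id=len(trains),
                                      trigger_time_s=ev.time_s,
                                      tap_times_s=tuple(taps),
                                      phase=PHASE_BASELINE))
            pending_taps.extend(taps)
    pending_taps.sort()

    def start_train(trigger_time: float, current_phase: str) -> TrainRecord:
        taps = plan_tap_train(trigger_time, cfg.tap_protocol, frame_interval_s=dt)
        rec = TrainRecord(train_id=len(trains), trigger_time_s=trigger_time,
                          tap_times_s=tuple(taps), phase=current_phase)
        trains.append(rec)
        pending_taps.extend(taps)
        pending_taps.sort()
        return rec

    for f in range(1, n_frames):
        lo, hi = (f - 1) * dt, f * dt
        taps_now = False
        while pending_taps and lo < pending_taps[0] <= hi:
            pending_taps.pop(0)
            taps_now = True

        value = worm.step(taps_now)
        sample = ActivitySample(t=f - 1, time_s=lo, value=float(value))

        if taps_now:
            notify_stimulus(state)
        _, decision = step_detector(state, sample)
        decisions.append(decision)

        # response assessment: raw criterion over the frames after the
        # last tap of the train (equivalent to assess_response on a state
        # snapshot; the refractory gate is ignored on purpose)
        def finalize_assessment():
            nonlocal awaiting, unresponsive_count, phase
            nonlocal extended_until, next_extended_train
            flags, _, rec = awaiting
            responsive = any(not met for met in flags)
            rec.responsive = responsive
            if responsive:
                unresponsive_count = 0
            else:
                unresponsive_count += 1
            awaiting = None
            if (phase == PHASE_CLOSED_LOOP
                    and unresponsive_count >= cfg.max_unresponsive_trains):
                phase = PHASE_EXTENDED
                extended_until = min(hi + cfg.extended.duration_s,
                                     n_frames * dt)
                next_extended_train = hi

        if awaiting is not None:
            flags, last_tap, _ = awaiting
            if sample.time_s >= last_tap:
                flags.append(decision.criterion_met)
            if len(flags) >= cfg.response_window_frames:
                finalize_assessment()

        # extended protocol: fixed-period trains, detection-independent
        if phase == PHASE_EXTENDED:
            assert extended_until is not None and next_extended_train is not None
            if hi >= extended_until:
                phase = PHASE_DONE
            elif hi >= next_extended_train:
                # trigger "now": staggering puts every tap strictly ahead
                start_train(hi, PHASE_EXTENDED)
                next_extended_train += cfg.extended.train_period_s

        # closed-loop trigger on a detected sleep bout.  The worm is
        # re-stimulated whenever it returns to sleep: a detection arriving
        # while a response assessment is still open cuts that assessment
        # short (its verdict comes from the frames already collected) and
        # launches the next train immediately.
        if (cfg.mode == "deprivation"
                and phase in (PHASE_BASELINE, PHASE_CLOSED_LOOP)
                and decision.asleep
                and not pending_taps):
            if awaiting is not None:
                finalize_assessment()
            if phase in (PHASE_BASELINE, PHASE_CLOSED_LOOP):
                phase = PHASE_CLOSED_LOOP
                rec = start_train(hi, phase)
                awaiting = [[], max(rec.tap_times_s), rec]

        phases.append(phase)

    log = ExperimentLog(decisions=decisions, phases=phases, trains=trains,
                        behavior=getattr(worm, "behavior_trace", lambda: None)(),
                        frame_interval_s=dt, config=cfg,
                        detector_params=detector_params)
    return log
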