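"""Frame schedules, time-activity curves and blood input functions.

Conventions
-----------
* Time origin is the tracer injection: ``t = 0`` at injection.  Imaging may
  begin before injection (the acquisition protocol starts the scanner 30 s
  early), so frame start times can be negative.
* Frame times in files and in :class:`FrameSchedule` are **seconds**
  post-injection; kinetic modelling converts to minutes internally.
* Activity concentrations are kBq/mL and are assumed decay-corrected to
  injection time; the decay factor appearing in the fit weighting is a pure
  count-statistics term.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunction",
    "build_schedule",
    "append_late_frames",
    "read_tac",
    "write_tac",
    "tumor_blood_ratio",
    "S1_SPEC",
    "S2_SPEC",
    "INJECTION_OFFSET_S",
    "LATE_FRAME_STARTS_S",
    "LATE_FRAME_DURATION_S",
    "s1_schedule",
    "s2_schedule",
]

#: Dynamic binning of the first 45 min of acquisition, as (count, duration-s)
#: pairs.  S1 is the tumor sequence, S2 the finer blood-pool sequence.
S1_SPEC = [(1, 30), (12, 5), (6, 10), (5, 30), (10, 60), (6, 300)]
S2_SPEC = [(1, 30), (60, 1), (12, 10), (3, 30), (10, 60), (6, 300)]

#: The tracer is injected 30 s after the scanner starts acquiring.
INJECTION_OFFSET_S = 30.0

#: Imaging resumes for single 10-min frames at 2 h and 4 h post-injection.
LATE_FRAME_STARTS_S = (7200.0, 14400.0)
LATE_FRAME_DURATION_S = 600.0


class ScheduleError(ValueError):
    """Raised for ill-formed frame schedules or TAC files."""


@dataclasses.dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing: start and duration of each frame, seconds.

    Frames must be time-ordered and non-overlapping; gaps are allowed
    (the 45-min dynamic block is followed by isolated late frames).
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ScheduleError("start and duration arrays must be 1-D and equal length")
        if start.size == 0:
            raise ScheduleError("schedule has no frames")
        if np.any(dur <= 0):
            raise ScheduleError("frame durations must be positive")
        ends = start + dur
        if np.any(start[1:] < ends[:-1] - 1e-9):
            raise ScheduleError("frames overlap or are out of order")

    @property
    def mid_s(self) -> np.ndarray:
        """Frame mid-times t_i, seconds post-injection."""
        return self.start_s + self.duration_s / 2.0

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    def __len__(self) -> int:
        return self.n_frames


@dataclasses.dataclass
class TimeActivityCurve:
    """Mean activity concentration per frame for one volume of interest."""

    schedule: FrameSchedule
    activity: np.ndarray  # kBq/mL per frame; negatives permitted (noise)
    decay_corrected: bool = True
    label: str = ""

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ScheduleError(
                f"activity length {self.activity.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.activity)):
            raise ScheduleError("activity values must be finite")

    def with_activity(self, activity: np.ndarray, label: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.schedule, activity, self.decay_corrected, self.label if label is None else label
        )

    def drop_frame(self, index: int) -> "TimeActivityCurve":
        """Return a copy with one frame removed (leave-one-out folds)."""
        keep = np.ones(self.schedule.n_frames, bool)
        keep[index] = False
        sched = FrameSchedule(self.schedule.start_s[keep], self.schedule.duration_s[keep])
        return TimeActivityCurve(sched, self.activity[keep], self.decay_corrected, self.label)


def build_schedule(spec, injection_offset: float = 0.0) -> FrameSchedule:
    """Build a contiguous schedule from (count, duration-s) pairs.

    The first frame starts at ``-injection_offset`` seconds: injection defines
    t = 0 and imaging may begin earlier.
    """
    starts, durs = [], []
    t = -float(injection_offset)
    for count, dur in spec:
        if count < 1:
            raise ScheduleError(f"frame count must be >= 1, got {count}")
        if dur <= 0:
            raise ScheduleError(f"frame duration must be positive, got {dur}")
        for _ in range(int(count)):
            starts.append(t)
            durs.append(float(dur))
            t += dur
    return FrameSchedule(np.array(starts), np.array(durs))


def append_late_frames(
    schedule: FrameSchedule,
    starts_s=LATE_FRAME_STARTS_S,
    duration_s: float = LATE_FRAME_DURATION_S,
) -> FrameSchedule:
    """Append isolated late frames (default: 10 min at 2 h and 4 h)."""
    start = np.concatenate([schedule.start_s, np.asarray(starts_s, float)])
    dur = np.concatenate([schedule.duration_s, np.full(len(starts_s), float(duration_s))])
    return FrameSchedule(start, dur)


def s1_schedule(late: bool = True) -> FrameSchedule:
    """The S1 tumor schedule, optionally with the 2 h / 4 h late frames."""
    sched = build_schedule(S1_SPEC, INJECTION_OFFSET_S)
    return append_late_frames(sched) if late else sched


def s2_schedule(late: bool = True) -> FrameSchedule:
    """The S2 blood-pool schedule, optionally with the 2 h / 4 h late frames."""
    sched = build_schedule(S2_SPEC, INJECTION_OFFSET_S)
    return append_late_frames(sched) if late else sched


# ---------------------------------------------------------------------------
# CSV I/O.  Fixed dialect: comma separator, dot decimal, UTF-8, mandatory
# header with columns frame_start_s, frame_duration_s, activity_kBq_ml.
# ---------------------------------------------------------------------------

_COLUMNS = ["frame_start_s", "frame_duration_s", "activity_kBq_ml"]


def read_tac(path) -> TimeActivityCurve:
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    for col in _COLUMNS:
        if col not in df.columns:
            raise ScheduleError(f"{path.name}: missing column {col!r}")
    start = df["frame_start_s"].to_numpy(float)
    dur = df["frame_duration_s"].to_numpy(float)
    ends = start + dur
    for i in range(1, len(start)):
        if start[i] < start[i - 1]:
            raise ScheduleError(f"{path.name}: frames unsorted at row {i}")
        if start[i] < ends[i - 1] - 1e-9:
            raise ScheduleError(f"{path.name}: overlapping frames at row {i}")
    sched = FrameSchedule(start, dur)
    return TimeActivityCurve(sched, df["activity_kBq_ml"].to_numpy(float), label=path.stem)


def write_tac(tac: TimeActivityCurve, path) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": tac.schedule.start_s,
            "frame_duration_s": tac.schedule.duration_s,
            "activity_kBq_ml": tac.activity,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


# ---------------------------------------------------------------------------
# Input function
# ---------------------------------------------------------------------------

#: Inter-node spacing (seconds) above which the blood curve is bridged with a
#: mono-exponential rather than linearly.  The densest in-block spacing of the
#: late dynamic frames is 300 s, so 600 s cleanly separates real gaps.
GAP_THRESHOLD_S = 600.0


class InputFunction:
    """Blood-pool concentration C_B(t) derived from a measured blood TAC.

    The interpolant is piecewise linear through the frame mid-time samples,
    rises linearly from 0 at injection to the first positive-time sample,
    bridges the 45 min -> 2 h -> 4 h acquisition gaps with a mono-exponential
    through the flanking samples (blood clearance at late times is slow and
    smooth; ``gap_mode="linear"`` selects straight bridging instead), and is
    held constant after the last sample.  C_B(t) = 0 for t <= 0.
    """

    def __init__(self, tac: TimeActivityCurve, gap_mode: str = "exponential"):
        if tac.schedule.n_frames == 0:
            raise ScheduleError("empty input function")
        if gap_mode not in ("exponential", "linear"):
            raise ValueError(f"unknown gap_mode {gap_mode!r}")
        self.tac = tac
        self.gap_mode = gap_mode
        mid = tac.schedule.mid_s
        keep = mid > 0
        if not np.any(keep):
            raise ScheduleError("input function has no post-injection frames")
        t_nodes = mid[keep]
        c_nodes = tac.activity[keep]
        self._knots_s, self._values = self._densify(t_nodes, c_nodes)

    def _densify(self, t_nodes, c_nodes):
        """Dense piecewise-linear knot representation of the interpolant."""
        ts = [0.0]
        cs = [0.0]
        prev_t, prev_c = 0.0, 0.0
        for t, c in zip(t_nodes, c_nodes):
            if (
                self.gap_mode == "exponential"
                and t - prev_t > GAP_THRESHOLD_S
                and prev_c > 0
                and c > 0
                and prev_t > 0
            ):
                # geometric (mono-exponential) bridge sampled onto sub-knots
                frac = np.linspace(0.0, 1.0, 26)[1:-1]
                tb = prev_t + frac * (t - prev_t)
                cb = prev_c * (c / prev_c) ** frac
                ts.extend(tb.tolist())
                cs.extend(cb.tolist())
            ts.append(float(t))
            cs.append(float(c))
            prev_t, prev_c = t, c
        # constant extension well past the last sample
        ts.append(ts[-1] + 4 * 3600.0)
        cs.append(cs[-1])
        return np.array(ts), np.array(cs)

    @property
    def knots_s(self) -> np.ndarray:
        return self._knots_s

    @property
    def knot_values(self) -> np.ndarray:
        return self._values

    def __call__(self, t_s) -> np.ndarray:
        """Interpolated blood concentration at time(s) t (seconds)."""
        t = np.asarray(t_s, dtype=float)
        out = np.interp(t, self._knots_s, self._values)
        out = np.where(t <= 0, 0.0, out)
        return out if out.ndim else float(out)


def interpolate_input(input_fn: InputFunction, t_s) -> np.ndarray:
    """Functional alias for ``input_fn(t_s)``."""
    return input_fn(t_s)


def tumor_blood_ratio(tumor_4h: float, blood_4h: float, threshold: float = 1.4) -> str:
    """Classify hypoxia status from the 4-h tumor-to-blood ratio.

    TBR above ``threshold`` (default 1.4) indicates hypoxia; TBR below 1
    indicates normoxia; values between are indeterminate.
    """
    if blood_4h <= 0:
        raise ValueError(f"blood activity must be positive, got {blood_4h}")
    ratio = tumor_4h / blood_4h
    if ratio > threshold:
        return "hypoxic"
    if ratio < 1.0:
        return "normoxic"
    return "indeterminate"
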