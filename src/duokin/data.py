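"""Core data containers for dynamic PET: frame schedules, time-activity
curves, arterial blood series, and physical decay correction.

Conventions shared by the whole package:

* time is stored in **seconds** post injection (reports convert to minutes),
* activity concentration is in **kBq/mL**,
* frames are half-open intervals ``[start, end)``; blood/HPLC samples are
  instantaneous time points,
* all activities entering the kinetic models are decay-corrected to the
  injection time (t = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "C11_HALF_LIFE_MIN",
    "ValidationError",
    "FrameSchedule",
    "make_frame_schedule",
    "HRRT_21_FRAME_SPEC",
    "TimeActivityCurve",
    "BloodSeries",
    "DecaySpec",
    "decay_correct",
    "decay_uncorrect",
]

#: Physical half-life of carbon-11 in minutes.
C11_HALF_LIFE_MIN = 20.364

#: 90-min dynamic schedule used throughout: 21 frames of increasing duration.
HRRT_21_FRAME_SPEC: tuple[tuple[int, float], ...] = (
    (3, 5.0),
    (3, 10.0),
    (4, 60.0),
    (2, 150.0),
    (2, 300.0),
    (7, 600.0),
)


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic-PET frames.

    Parameters
    ----------
    start, end : array-like
        Frame start/end times in seconds post injection.  Frames must be
        contiguous (each start equals the previous end), strictly increasing
        and of positive duration.
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        start = _as_float_array(self.start, "start")
        end = _as_float_array(self.end, "end")
        if start.size == 0:
            raise ValidationError("a frame schedule needs at least one frame")
        if start.size != end.size:
            raise ValidationError("start and end must have equal length")
        if np.any(end <= start):
            raise ValidationError("all frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValidationError("frame starts must be strictly increasing")
        if not np.allclose(start[1:], end[:-1], rtol=0.0, atol=1e-9):
            raise ValidationError("frames must be contiguous (start[i+1] == end[i])")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times in seconds, exactly ``(start + end) / 2``."""
        return (self.start + self.end) / 2.0

    @property
    def duration(self) -> np.ndarray:
        """Frame durations in seconds."""
        return self.end - self.start

    @property
    def total_duration(self) -> float:
        """Scan length in seconds (end of the last frame)."""
        return float(self.end[-1])

    def __len__(self) -> int:
        return self.n_frames


def make_frame_schedule(
    spec: Sequence[tuple[int, float]] = HRRT_21_FRAME_SPEC,
) -> FrameSchedule:
    """Build a contiguous schedule from ``(count, duration_seconds)`` groups.

    The default reproduces the 21-frame, 90-min protocol
    (3 x 5 s, 3 x 10 s, 4 x 60 s, 2 x 150 s, 2 x 300 s, 7 x 600 s).

    Examples
    --------
    >>> sched = make_frame_schedule()
    >>> sched.n_frames, sched.total_duration
    (21, 5385.0)
    """
    if len(spec) == 0:
        raise ValidationError("empty frame specification")
    durations: list[float] = []
    for count, dur in spec:
        if count < 1:
            raise ValidationError(f"frame count must be >= 1, got {count}")
        if dur <= 0:
            raise ValidationError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    end = np.cumsum(durations)
    start = np.concatenate([[0.0], end[:-1]])
    return FrameSchedule(start=start, end=end)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration over time, per frame or per sample.

    Either ``schedule`` (frame-averaged data) or ``times`` (instantaneous
    samples) must be given, not both.  NaN activities are allowed only for
    explicitly flagged missing samples.
    """

    activity: np.ndarray
    schedule: FrameSchedule | None = None
    times: np.ndarray | None = None
    decay_corrected: bool = True
    region: str = ""
    missing: np.ndarray | None = None  # boolean mask of flagged missing samples

    def __post_init__(self):
        act = _as_float_array(self.activity, "activity")
        if (self.schedule is None) == (self.times is None):
            raise ValidationError("exactly one of schedule or times must be set")
        if self.schedule is not None:
            n = self.schedule.n_frames
        else:
            t = _as_float_array(self.times, "times")
            if np.any(np.diff(t) <= 0):
                raise ValidationError("sample times must be strictly increasing")
            object.__setattr__(self, "times", t)
            n = t.size
        if act.size != n:
            raise ValidationError(
                f"activity length {act.size} does not match time axis length {n}"
            )
        miss = self.missing
        if miss is None:
            miss = np.zeros(n, dtype=bool)
        else:
            miss = np.asarray(miss, dtype=bool)
        if np.any(~np.isfinite(act) & ~miss):
            raise ValidationError("non-finite activity at a non-flagged sample")
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "missing", miss)

    @property
    def t(self) -> np.ndarray:
        """Representative times in seconds (frame mids for frame data)."""
        return self.schedule.mid if self.schedule is not None else self.times

    def __len__(self) -> int:
        return self.activity.size


@dataclass(frozen=True)
class BloodSeries:
    """Arterial whole-blood and plasma activity samples.

    ``source`` labels each sample ``"continuous"`` (automated sampling
    system) or ``"manual"`` (discrete hand-drawn samples); times must be
    strictly increasing within each source.
    """

    times: np.ndarray  # seconds
    whole_blood: np.ndarray  # kBq/mL
    plasma: np.ndarray  # kBq/mL
    source: np.ndarray  # str array: "continuous" | "manual"

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        wb = _as_float_array(self.whole_blood, "whole_blood")
        pl = _as_float_array(self.plasma, "plasma")
        src = np.asarray(self.source)
        if src.ndim == 0:
            src = np.full(t.size, str(src))
        if not (t.size == wb.size == pl.size == src.size):
            raise ValidationError("blood series columns must have equal length")
        bad = set(np.unique(src)) - {"continuous", "manual"}
        if bad:
            raise ValidationError(f"unknown blood sample source(s): {sorted(bad)}")
        if np.any(wb < 0) or np.any(pl < 0):
            raise ValidationError("blood activities must be non-negative")
        for s in ("continuous", "manual"):
            ts = t[src == s]
            if ts.size > 1 and np.any(np.diff(ts) <= 0):
                raise ValidationError(f"{s} sample times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "whole_blood", wb)
        object.__setattr__(self, "plasma", pl)
        object.__setattr__(self, "source", src)

    def subset(self, mask: np.ndarray) -> "BloodSeries":
        return BloodSeries(
            self.times[mask], self.whole_blood[mask], self.plasma[mask], self.source[mask]
        )

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DecaySpec:
    """Isotope decay constant and reference time for decay correction.

    The default half-life is carbon-11; the reference time is injection
    (t = 0), to which all activities are corrected before modelling.
    """

    half_life_min: float = C11_HALF_LIFE_MIN
    reference_time_s: float = 0.0

    def __post_init__(self):
        if self.half_life_min <= 0:
            raise ValidationError("half-life must be positive")

    def factor(self, t_seconds: np.ndarray) -> np.ndarray:
        """Decay-correction factor exp(ln2 * (t - t_ref) / T_half)."""
        dt_min = (np.asarray(t_seconds, dtype=float) - self.reference_time_s) / 60.0
        return np.exp(np.log(2.0) * dt_min / self.half_life_min)


def decay_correct(tac: TimeActivityCurve, spec: DecaySpec = DecaySpec()) -> TimeActivityCurve:
    """Decay-correct a measured curve to the injection time.

    Frame data are corrected at their mid-times; sample data at their sample
    times.  Correcting an already-corrected curve raises, so the flag is a
    reliable provenance record.
    """
    if tac.decay_corrected:
        raise ValidationError("curve is already decay-corrected")
    fac = spec.factor(tac.t)
    return replace(tac, activity=tac.activity * fac, decay_corrected=True)


def decay_uncorrect(tac: TimeActivityCurve, spec: DecaySpec = DecaySpec()) -> TimeActivityCurve:
    """Inverse of :func:`decay_correct`; restores measured activities."""
    if not tac.decay_corrected:
        raise ValidationError("curve is not decay-corrected")
    fac = spec.factor(tac.t)
    return replace(tac, activity=tac.activity / fac, decay_corrected=False)
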