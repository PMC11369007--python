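"""PET frame schedules and regional time-activity curves.

All times are minutes internally; file interfaces use seconds (see
:mod:`petdisplace.io`). A dynamic PET acquisition is described by a
:class:`FrameSchedule` (contiguous or gapped, sorted, non-overlapping
frames) and a :class:`TimeActivityCurve` holds the decay-corrected
tissue concentration of one region, one value per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "TimeActivityCurve"]


@dataclass(frozen=True)
class FrameSchedule:
    """Frame start/end times of a dynamic PET scan, in minutes."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.atleast_1d(np.asarray(self.start, dtype=float))
        end = np.atleast_1d(np.asarray(self.end, dtype=float))
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.shape != end.shape or start.ndim != 1 or start.size == 0:
            raise ValueError("start and end must be equal-length 1-d arrays")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise ValueError("frame times must be finite")
        if not np.all(end > start):
            raise ValueError("every frame must end after it starts")
        if not np.all(np.diff(start) > 0):
            raise ValueError("frames must be sorted by start time")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        if self.total_duration <= 0:
            raise ValueError("total duration must be positive")

    @classmethod
    def from_seconds(cls, start_s, end_s) -> "FrameSchedule":
        return cls(np.asarray(start_s, float) / 60.0, np.asarray(end_s, float) / 60.0)

    @classmethod
    def from_durations_s(cls, durations_s) -> "FrameSchedule":
        """Build a contiguous schedule (starting at 0) from frame durations in seconds."""
        end = np.cumsum(np.asarray(durations_s, dtype=float)) / 60.0
        start = end - np.asarray(durations_s, dtype=float) / 60.0
        return cls(start, end)

    @classmethod
    def ucbj_120min(cls) -> "FrameSchedule":
        """The 36-frame, 120-min schedule used for [11C]UCB-J displacement studies.

        8 x 15 s, 8 x 30 s, 4 x 60 s, 5 x 120 s, 2 x 300 s and 9 x 600 s.
        """
        durations = [15] * 8 + [30] * 8 + [60] * 4 + [120] * 5 + [300] * 2 + [600] * 9
        return cls.from_durations_s(durations)

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def duration(self) -> np.ndarray:
        """Frame durations, minutes."""
        return self.end - self.start

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints, minutes."""
        return 0.5 * (self.start + self.end)

    @property
    def total_duration(self) -> float:
        return float(self.end[-1] - self.start[0])

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.start.shape == other.start.shape
            and np.allclose(self.start, other.start)
            and np.allclose(self.end, other.end)
        )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-wise activity concentration (kBq/mL) of one brain region.

    ``activity`` is the decay-corrected concentration measured in the PET
    image, i.e. the tissue signal plus the fractional-blood-volume
    contribution; it is the target of the kinetic fits.
    """

    region: str
    schedule: FrameSchedule
    activity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        activity = np.atleast_1d(np.asarray(self.activity, dtype=float))
        object.__setattr__(self, "activity", activity)
        if not self.region:
            raise ValueError("region label must be non-empty")
        if activity.ndim != 1 or activity.size != self.schedule.n_frames:
            raise ValueError(
                f"activity length {activity.size} does not match "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(activity)):
            raise ValueError("activity must be finite")

    def truncated(self, t_max: float) -> "TimeActivityCurve":
        """Keep only frames that end at or before ``t_max`` minutes."""
        keep = self.schedule.end <= t_max + 1e-9
        if not np.any(keep):
            raise ValueError(f"no frames end at or before t_max={t_max}")
        sched = FrameSchedule(self.schedule.start[keep], self.schedule.end[keep])
        return TimeActivityCurve(self.region, sched, self.activity[keep])
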