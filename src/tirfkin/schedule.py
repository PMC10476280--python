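"""Acquisition schedules: the common time base for multi-channel time-lapse imaging.

A CoSMoS experiment interleaves channels at different cadences — a slow
DNA-marker channel that only anchors spot positions, and fast protein
channels whose frames define the kinetic time grid.  Every downstream
quantity (pulse onsets, durations, censoring) lives on these grids, so the
schedule is constructed once and shared by the simulator and the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionSchedule", "DEFAULT_CHANNEL_INTERVALS"]

#: channel label -> frame interval (s); wavelengths follow common CoSMoS
#: usage (647 nm = DNA/reference dye, 488/561 nm = protein labels)
DEFAULT_CHANNEL_INTERVALS: dict[str, float] = {"647": 60.0, "488": 5.0, "561": 5.0}


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Per-channel frame times for one acquisition.

    Frames for a channel with interval ``dt`` fall at ``0, dt, 2*dt, ...``
    up to and including ``total_duration`` when it lies on the grid, so a
    45-min acquisition at 5 s cadence has ``floor(2700/5) + 1 = 541`` frames.

    Parameters
    ----------
    total_duration
        Acquisition span in seconds (default 2700 s = 45 min).
    channel_intervals
        Mapping channel label -> frame interval in seconds.
    """

    total_duration: float = 2700.0
    channel_intervals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_INTERVALS)
    )

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if not self.channel_intervals:
            raise ValueError("at least one channel is required")
        for label, dt in self.channel_intervals.items():
            if dt <= 0:
                raise ValueError(f"channel {label!r}: frame interval must be positive")
            if dt > self.total_duration:
                raise ValueError(
                    f"channel {label!r}: interval {dt} s exceeds total duration"
                )

    @property
    def channels(self) -> list[str]:
        return list(self.channel_intervals)

    def interval(self, channel: str) -> float:
        return self.channel_intervals[channel]

    def n_frames(self, channel: str) -> int:
        dt = self.channel_intervals[channel]
        # floor on an exact grid; guard against float fuzz (2700/5 -> 540.0000...)
        return int(np.floor(self.total_duration / dt + 1e-9)) + 1

    def frame_times(self, channel: str) -> np.ndarray:
        """Ordered frame times (s) for a channel, starting at 0."""
        dt = self.channel_intervals[channel]
        return np.arange(self.n_frames(channel)) * dt

    def to_dict(self) -> dict:
        return {
            "total_duration": self.total_duration,
            "channel_intervals": dict(self.channel_intervals),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        return cls(
            total_duration=float(d["total_duration"]),
            channel_intervals={k: float(v) for k, v in d["channel_intervals"].items()},
        )
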