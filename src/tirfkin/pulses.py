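"""ON/OFF pulse detection on z-normalized traces, plus photobleach step counting.

A pulse is one contiguous residence of a labeled protein at a spot: maximal
run of above-threshold frames (optionally bridging brief OFF gaps and
discarding runs shorter than a minimum).  Durations are frame-quantized:
each detected frame contributes one full frame interval, so a single-frame
event lasts exactly one interval and all durations sit on the acquisition
grid.  Runs touching the last frame are right-censored (the molecule
outlived the movie); runs touching the first frame are flagged
present-at-start but are not additionally censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import Trace

__all__ = [
    "Pulse",
    "BinarizationPolicy",
    "binarize_trace",
    "derive_pulses",
    "pulses_from_trace",
    "count_bleach_steps",
    "pulses_to_frame",
    "pulses_from_frame",
]


@dataclass(frozen=True)
class Pulse:
    """One contiguous ON residence of a protein at a spot."""

    spot: int
    channel: str
    onset: float  # s, time of the first ON frame
    duration: float  # s, ON-frame count x frame interval
    right_censored: bool  # still ON at the final frame
    present_at_start: bool  # already ON at the first frame

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def overlaps(self, other: "Pulse") -> bool:
        """True if the two half-open spans [onset, end) intersect."""
        return self.onset < other.end and other.onset < self.end


@dataclass(frozen=True)
class BinarizationPolicy:
    """Channel-level thresholding and run-cleaning rules.

    ``z_threshold`` is in robust-z units (MADs above baseline);
    ``min_on_frames`` discards runs shorter than that many frames;
    ``max_gap_frames`` bridges OFF gaps of at most that many frames inside a
    run (bridged frames count toward the duration).
    """

    z_threshold: float = 3.0
    min_on_frames: int = 2
    max_gap_frames: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_threshold) and self.z_threshold != -np.inf:
            raise ValueError("z_threshold must be finite or -inf")
        if self.min_on_frames < 1:
            raise ValueError("min_on_frames must be >= 1")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


def binarize_trace(trace: Trace, policy: BinarizationPolicy) -> np.ndarray:
    """Frame-wise ON/OFF: frame i is ON iff z[i] >= threshold.

    Non-finite z-values are treated as OFF (with a warning) so corrupt
    frames cannot seed pulses.
    """
    z = np.asarray(trace.z, dtype=float)
    bad = ~np.isfinite(z)
    if bad.any():
        warnings.warn(
            f"trace (spot {trace.spot}, channel {trace.channel}): "
            f"{int(bad.sum())} non-finite frames treated as OFF",
            stacklevel=2,
        )
        z = np.where(bad, -np.inf, z)
    return z >= policy.z_threshold


def _runs(on: np.ndarray) -> list[tuple[int, int]]:
    """Maximal ON runs as (first, last) inclusive frame indices."""
    idx = np.flatnonzero(on)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def derive_pulses(
    on_series: np.ndarray,
    frame_times: np.ndarray,
    policy: BinarizationPolicy,
    spot: int = 0,
    channel: str = "",
    frame_interval: float | None = None,
) -> list[Pulse]:
    """Convert a boolean frame series into Pulses on the frame grid.

    Gap bridging happens first (OFF gaps of at most ``max_gap_frames``
    frames between ON runs are absorbed, and the bridged frames count as
    ON), then runs shorter than ``min_on_frames`` frames are discarded.
    """
    on = np.asarray(on_series, dtype=bool)
    frame_times = np.asarray(frame_times, dtype=float)
    if len(on) != len(frame_times):
        raise ValueError("series and frame grid differ in length")
    if len(on) == 0:
        return []
    if frame_interval is not None:
        interval = float(frame_interval)
    elif len(frame_times) > 1:
        interval = float(frame_times[1] - frame_times[0])
    else:
        raise ValueError("frame_interval required for a single-frame series")
    runs = _runs(on)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 <= policy.max_gap_frames:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    pulses: list[Pulse] = []
    last = len(on) - 1
    for a, b in merged:
        n_frames = b - a + 1
        if n_frames < policy.min_on_frames:
            continue
        pulses.append(
            Pulse(
                spot=spot,
                channel=channel,
                onset=float(frame_times[a]),
                duration=n_frames * interval,
                right_censored=(b == last),
                present_at_start=(a == 0),
            )
        )
    return pulses


def pulses_from_trace(trace: Trace, policy: BinarizationPolicy) -> list[Pulse]:
    """binarize_trace + derive_pulses in one step."""
    on = binarize_trace(trace, policy)
    return derive_pulses(on, trace.frame_times, policy, trace.spot, trace.channel)


# ---------------------------------------------------------------------------
# photobleach step counting

def _binary_segmentation(
    x: np.ndarray, penalty: float, min_size: int = 2
) -> list[int]:
    """Change-points by recursive binary segmentation of a piecewise-constant
    least-squares model; a split is kept while it reduces SSE by > penalty."""

    def best_split(a: int, b: int) -> tuple[float, int]:
        seg = x[a:b]
        n = len(seg)
        if n < 2 * min_size:
            return 0.0, -1
        csum = np.cumsum(seg)
        csq = np.cumsum(seg**2)
        total_sse = csq[-1] - csum[-1] ** 2 / n
        ks = np.arange(min_size, n - min_size + 1)
        left_sse = csq[ks - 1] - csum[ks - 1] ** 2 / ks
        rs = csum[-1] - csum[ks - 1]
        rq = csq[-1] - csq[ks - 1]
        right_sse = rq - rs**2 / (n - ks)
        gain = total_sse - (left_sse + right_sse)
        j = int(np.argmax(gain))
        return float(gain[j]), a + int(ks[j])

    cps: list[int] = []
    stack = [(0, len(x))]
    while stack:
        a, b = stack.pop()
        gain, k = best_split(a, b)
        if k >= 0 and gain > penalty:
            cps.append(k)
            stack.append((a, k))
            stack.append((k, b))
    return sorted(cps)


def count_bleach_steps(
    intensity: np.ndarray,
    min_drop_frac: float = 0.2,
    penalty_scale: float = 3.0,
) -> int:
    """Count downward intensity steps in a photobleaching staircase.

    Fits a piecewise-constant model by penalized binary segmentation
    (penalty = ``penalty_scale`` * sigma^2 * log n, sigma from temporal first
    differences), then counts segment-to-segment decreases of at least
    ``min_drop_frac`` of the initial above-baseline amplitude.  Traces with
    no resolvable structure (flat, or never above baseline) score 0.
    """
    x = np.asarray(intensity, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        return 0
    sigma = 1.4826 * float(np.median(np.abs(np.diff(x)))) / np.sqrt(2.0)
    if sigma == 0.0:
        sigma = 1e-9
    penalty = penalty_scale * sigma**2 * np.log(len(x))
    cps = _binary_segmentation(x, penalty)
    bounds = [0, *cps, len(x)]
    means = [float(np.mean(x[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    initial = means[0] - min(means)
    if initial <= 0:
        return 0
    min_drop = min_drop_frac * initial
    steps = 0
    prev = means[0]
    for m in means[1:]:
        if prev - m >= min_drop:
            steps += 1
            prev = m
        elif m > prev:  # blinking back up resets the reference level
            prev = m
    return steps


# ---------------------------------------------------------------------------
# serialization

_PULSE_COLUMNS = [
    "spot",
    "channel",
    "onset_s",
    "end_s",
    "duration_s",
    "right_censored",
    "present_at_start",
]


def pulses_to_frame(pulses: list[Pulse]) -> pd.DataFrame:
    """One row per pulse, in the event-raster column layout."""
    rows = [
        (p.spot, p.channel, p.onset, p.end, p.duration, p.right_censored, p.present_at_start)
        for p in pulses
    ]
    return pd.DataFrame(rows, columns=_PULSE_COLUMNS)


def pulses_from_frame(df: pd.DataFrame) -> list[Pulse]:
    return [
        Pulse(
            spot=int(r.spot),
            channel=str(r.channel),
            onset=float(r.onset_s),
            duration=float(r.duration_s),
            right_censored=bool(r.right_censored),
            present_at_start=bool(r.present_at_start),
        )
        for r in df.itertuples()
    ]
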