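"""Core in-memory containers shared across the pipeline.

A :class:`GaitCycle` holds the three sensed channels of one activity cycle
from a thigh-mounted device: forward acceleration ``ax`` and vertical
acceleration ``ay`` (m/s^2, gravity removed) and the sagittal-plane angular
velocity ``gz`` (rad/s). A :class:`SessionRecording` is a continuous log of
the same channels with optional ground-truth segment annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activities import ActivityLabel


def _as_channel(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"channel {name!r} must be 1-D, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"channel {name!r} contains non-finite values")
    return arr


@dataclass
class GaitCycle:
    """One activity cycle's aligned sensor channels.

    Parameters
    ----------
    ax, ay : ndarray, m/s^2
        Forward and vertical linear acceleration (gravity excluded).
    gz : ndarray, rad/s
        Angular velocity about the lateral axis (sagittal-plane rotation).
    f_sample : float, Hz
        Sampling rate of all three channels.
    label : ActivityLabel, optional
        Ground-truth activity, if known.
    """

    ax: np.ndarray
    ay: np.ndarray
    gz: np.ndarray
    f_sample: float
    label: ActivityLabel | None = None

    def __post_init__(self) -> None:
        self.ax = _as_channel(self.ax, "ax")
        self.ay = _as_channel(self.ay, "ay")
        self.gz = _as_channel(self.gz, "gz")
        if not (len(self.ax) == len(self.ay) == len(self.gz)):
            raise ValueError(
                "channels must have equal length, got "
                f"{len(self.ax)}/{len(self.ay)}/{len(self.gz)}"
            )
        if self.f_sample <= 0:
            raise ValueError(f"f_sample must be positive, got {self.f_sample}")
        if self.label is not None:
            self.label = ActivityLabel.coerce(self.label)

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def duration(self) -> float:
        """Cycle duration in seconds."""
        return self.n_samples / self.f_sample

    @property
    def asag(self) -> np.ndarray:
        """Sagittal-plane acceleration magnitude sqrt(ax^2 + ay^2)."""
        return np.hypot(self.ax, self.ay)


@dataclass(frozen=True)
class SegmentAnnotation:
    """A labeled half-open sample-index interval [start, end) of a recording."""

    start: int
    end: int
    label: ActivityLabel

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        object.__setattr__(self, "label", ActivityLabel.coerce(self.label))

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Number of samples shared with another half-open interval."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class SessionRecording:
    """A continuous multi-activity sensor log sampled uniformly at f_sample.

    ``segments`` carries ground truth for synthetic sessions (each activity
    cycle annotated; rest left unannotated) and is empty for real logs.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    gz: np.ndarray
    f_sample: float
    segments: list[SegmentAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = _as_channel(self.t, "t")
        self.ax = _as_channel(self.ax, "ax")
        self.ay = _as_channel(self.ay, "ay")
        self.gz = _as_channel(self.gz, "gz")
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.gz) == n):
            raise ValueError("t, ax, ay, gz must have equal length")
        prev_end = 0
        for seg in self.segments:
            if seg.start < prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            if seg.end > n:
                raise ValueError(f"segment {seg} exceeds recording length {n}")
            prev_end = seg.end

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def asag(self) -> np.ndarray:
        """Sagittal-plane acceleration magnitude sqrt(ax^2 + ay^2)."""
        return np.hypot(self.ax, self.ay)

    def slice_cycle(self, start: int, end: int, label=None) -> GaitCycle:
        """Extract the half-open sample range [start, end) as a GaitCycle."""
        if not (0 <= start < end <= self.n_samples):
            raise ValueError(f"invalid slice [{start}, {end})")
        return GaitCycle(
            ax=self.ax[start:end].copy(),
            ay=self.ay[start:end].copy(),
            gz=self.gz[start:end].copy(),
            f_sample=self.f_sample,
            label=label,
        )
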