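"""CSV I/O for sensor logs and segment-annotation files.

Two plain-text formats, both UTF-8, '.' decimal, newline-terminated:

* sensor log — header ``t,ax,ay,az,gx,gy,gz``; time in seconds, strictly
  increasing; accelerations in m/s^2, angular velocities in rad/s. Only
  ``t, ax, ay, gz`` are consumed downstream (the device frame is x forward,
  y up, z right, so sagittal-plane motion lives in exactly these three);
  the remaining channels are written as 0 when absent.
* labels — header ``start,end,label`` with 0-based half-open sample-index
  intervals and snake_case activity names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .activities import ActivityLabel, UnknownLabelError  # noqa: F401  (re-export)
from .core import SegmentAnnotation, SessionRecording

LOG_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
REQUIRED_LOG_COLUMNS = ("t", "ax", "ay", "gz")
LABEL_COLUMNS = ("start", "end", "label")


class MissingColumnError(ValueError):
    """A required CSV column is absent."""


class NonMonotoneTimeError(ValueError):
    """Timestamps in a sensor log are not strictly increasing."""


def read_log(path, f_sample: float | None = None) -> SessionRecording:
    """Read a sensor-log CSV into a SessionRecording.

    If ``f_sample`` is not given it is inferred as ``1 / median(dt)``;
    a log with fewer than two samples then gets ``f_sample = nan``.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_LOG_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(
                f"sensor log {path} is missing required column {col!r}"
            )
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise NonMonotoneTimeError(
                f"time column must be strictly increasing; violation at row {bad}"
            )
        if f_sample is None:
            f_sample = 1.0 / float(np.median(dt))
    elif f_sample is None:
        f_sample = float("nan")
    return SessionRecording(
        t=t,
        ax=df["ax"].to_numpy(dtype=float),
        ay=df["ay"].to_numpy(dtype=float),
        gz=df["gz"].to_numpy(dtype=float),
        f_sample=f_sample,
    )


def write_log(recording: SessionRecording, path, sig_digits: int = 9) -> None:
    """Write a SessionRecording as a sensor-log CSV.

    Channels the recording does not carry (az, gx, gy) are written as 0.
    ``sig_digits`` controls the significant digits of float formatting.
    """
    n = recording.n_samples
    zeros = np.zeros(n)
    df = pd.DataFrame(
        {
            "t": recording.t,
            "ax": recording.ax,
            "ay": recording.ay,
            "az": zeros,
            "gx": zeros,
            "gy": zeros,
            "gz": recording.gz,
        },
        columns=list(LOG_COLUMNS),
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{sig_digits}g", lineterminator="\n")


def read_labels(path) -> list[SegmentAnnotation]:
    """Read segment annotations (``start,end,label``) in file order."""
    df = pd.read_csv(path)
    for col in LABEL_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(
                f"label file {path} is missing required column {col!r}"
            )
    return [
        SegmentAnnotation(int(row.start), int(row.end), ActivityLabel.from_key(row.label))
        for row in df.itertuples(index=False)
    ]


def write_labels(annotations, path) -> None:
    """Write segment annotations as a ``start,end,label`` CSV."""
    df = pd.DataFrame(
        {
            "start": [a.start for a in annotations],
            "end": [a.end for a in annotations],
            "label": [a.label.key for a in annotations],
        },
        columns=list(LABEL_COLUMNS),
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def slice_labeled_cycles(recording: SessionRecording, annotations=None):
    """Cut a recording into labeled GaitCycles along its annotations."""
    if annotations is None:
        annotations = recording.segments
    return [
        recording.slice_cycle(a.start, a.end, a.label) for a in annotations
    ]
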