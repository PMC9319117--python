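"""Online segmentation and classification of a continuous recording.

The detector walks causally through the log. From the current start
position it looks at most one maximum-cycle-period ahead, finds peaks of
the sagittal acceleration magnitude inside that window, and for each peak
searches forward for a cycle-end candidate — by default the next
zero-crossing of the sagittal angular velocity G_z (the thigh reverses its
rotation between movement phases), alternatively the point where A_sag
settles below a rest threshold. Every candidate segment
[start, end) whose duration is plausible for a single cycle and short
enough for the spectral window is featurized and scored by the trained
network; the best-probability candidate is emitted as a detection event if
its probability clears the acceptance threshold, and the detector jumps to
its end. Otherwise it advances to the nearest candidate end (configurably
the second-to-last, or a full window when there are no candidates), so the
start index strictly increases every iteration and the loop terminates on
any finite input. Rest and other unmodeled movement are never emitted:
they simply fail the probability gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .activities import ActivityLabel
from .core import GaitCycle, SessionRecording
from .features import extract_features, sagittal_magnitude

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Settings of the online detection loop.

    Parameters
    ----------
    f_sample : Hz — sampling rate of the incoming log.
    period_max_cycle : s — longest plausible activity cycle; it sizes the
        peak-search window (numMaxCycleSample = f_sample * period_max_cycle),
        so candidates longer than any real cycle cannot arise.
    min_cycle_duration : s — shortest plausible cycle; shorter candidate
        segments are never scored (sub-cycle fragments otherwise attract
        spuriously confident classifications).
    acceptable_accuracy : minimum class probability required to emit an
        event (in (0, 1]).
    peak_min_height : m/s^2 or None — minimum A_sag peak height. The
        default absolute floor keeps sensor noise during rest from seeding
        candidates; None selects an adaptive mean + 1 sd of the window.
    peak_min_separation : s — minimum spacing between accepted peaks.
    end_mode : "gyro_zero_cross" (default) or "sagittal_rest".
    rest_threshold : m/s^2 — A_sag level counted as rest (sagittal_rest mode).
    rest_min_samples : consecutive sub-threshold samples required.
    reject_advance : where the start index moves when no candidate clears
        the gate: "nearest" (first candidate end — small steps re-anchor
        the detector quickly) or "second_last" (jump near the window end).
    n_exp, n_orders : spectral feature parameters; candidate segments
        longer than 2**n_exp samples are skipped, never truncated.
    """

    f_sample: float = 16.0
    period_max_cycle: float = 3.0
    min_cycle_duration: float = 0.7
    acceptable_accuracy: float = 0.90
    peak_min_height: float | None = 0.3
    peak_min_separation: float = 0.25
    end_mode: str = "gyro_zero_cross"
    rest_threshold: float = 0.3
    rest_min_samples: int = 2
    reject_advance: str = "nearest"
    n_exp: int = 6
    n_orders: int = 6

    def __post_init__(self) -> None:
        if self.f_sample <= 0 or self.period_max_cycle <= 0:
            raise ValueError("f_sample and period_max_cycle must be positive")
        if self.min_cycle_duration < 0:
            raise ValueError("min_cycle_duration must be >= 0")
        if not 0 < self.acceptable_accuracy <= 1:
            raise ValueError("acceptable_accuracy must be in (0, 1]")
        if self.end_mode not in ("gyro_zero_cross", "sagittal_rest"):
            raise ValueError(f"unknown end_mode {self.end_mode!r}")
        if self.reject_advance not in ("nearest", "second_last"):
            raise ValueError(f"unknown reject_advance {self.reject_advance!r}")

    @property
    def window_samples(self) -> int:
        """numMaxCycleSample = f_sample * period_max_cycle."""
        return max(1, int(round(self.f_sample * self.period_max_cycle)))

    @property
    def max_segment_samples(self) -> int:
        return 2 ** self.n_exp


@dataclass(frozen=True)
class DetectionEvent:
    """One emitted activity: half-open sample interval, label, confidence."""

    start: int
    end: int
    label: ActivityLabel
    probability: float
    probabilities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")


def find_peaks_in_window(
    signal,
    start: int,
    window_length: int,
    min_height: float | None = None,
    min_separation_samples: int = 1,
) -> np.ndarray:
    """Local maxima of ``signal[start : start+window_length]`` (clipped at
    the series end), as absolute indices sorted ascending.

    Peaks must exceed ``min_height`` (default: window mean + 1 sd) and be
    at least ``min_separation_samples`` apart; of two closer peaks the
    larger wins. Window endpoints never count as peaks.
    """
    signal = np.asarray(signal, dtype=float)
    start = max(0, int(start))
    stop = min(len(signal), start + int(window_length))
    window = signal[start:stop]
    if len(window) < 3:
        return np.empty(0, dtype=int)
    if min_height is None:
        min_height = float(window.mean() + window.std())
    locs, _ = _scipy_find_peaks(
        window, height=min_height, distance=max(1, int(min_separation_samples))
    )
    return locs + start


def search_end_locations(
    asag, gz, peak_locations, config: DetectionConfig
) -> np.ndarray:
    """Cycle-end candidate for each peak: the first index after the peak
    where the end criterion fires, or the series length if it never does.

    gyro_zero_cross mode fires at a sign change of G_z between consecutive
    samples (the returned index is the sample after the change);
    sagittal_rest mode fires where A_sag stays below the rest threshold
    for the configured number of samples. The result is sorted and
    deduplicated.
    """
    asag = np.asarray(asag, dtype=float)
    gz = np.asarray(gz, dtype=float)
    n = len(gz)
    peaks = np.asarray(peak_locations, dtype=int)
    if peaks.size == 0:
        return np.empty(0, dtype=int)
    if config.end_mode == "gyro_zero_cross":
        crossings = np.flatnonzero(gz[1:] * gz[:-1] < 0.0) + 1
    else:
        below = asag < config.rest_threshold
        m = config.rest_min_samples
        runs = np.ones(len(below), dtype=bool)
        for off in range(m):
            shifted = np.zeros(len(below), dtype=bool)
            shifted[: len(below) - off] = below[off:]
            runs &= shifted
        crossings = np.flatnonzero(runs)
    ends = []
    for p in peaks:
        after = crossings[crossings > p]
        ends.append(int(after[0]) if after.size else n)
    return np.unique(np.asarray(ends, dtype=int))


def detect_activities(
    session: SessionRecording,
    model,
    config: DetectionConfig | None = None,
) -> list[DetectionEvent]:
    """Run the online detection loop over a whole recording.

    Returns time-ordered, non-overlapping events whose class probability
    is at least ``config.acceptable_accuracy``.
    """
    if config is None:
        config = DetectionConfig(f_sample=session.f_sample)
    if session.n_samples == 0:
        return []
    asag = sagittal_magnitude(session.ax, session.ay)
    gz = session.gz
    n_total = session.n_samples
    window = config.window_samples
    sep = max(1, int(round(config.peak_min_separation * config.f_sample)))
    min_len = max(2, int(round(config.min_cycle_duration * config.f_sample)))
    events: list[DetectionEvent] = []
    start = 0
    while start < n_total:
        peaks = find_peaks_in_window(
            asag, start, window,
            min_height=config.peak_min_height,
            min_separation_samples=sep,
        )
        ends = search_end_locations(asag, gz, peaks, config)
        ends = ends[ends > start]
        best_end, best_proba, best_p = None, None, -1.0
        for e in ends:
            seg_len = int(e) - start
            if seg_len < min_len:
                continue
            if seg_len > config.max_segment_samples:
                logger.warning(
                    "skipping candidate [%d, %d): %d samples exceed the "
                    "2**%d spectral window", start, e, seg_len, config.n_exp,
                )
                continue
            cycle = GaitCycle(
                ax=session.ax[start:e], ay=session.ay[start:e],
                gz=gz[start:e], f_sample=session.f_sample,
            )
            x = extract_features(cycle, n_exp=config.n_exp, n_orders=config.n_orders)
            proba = model.predict_proba(x[None, :])[0]
            p = float(proba.max())
            if p > best_p:
                best_end, best_proba, best_p = int(e), proba, p
        if best_end is not None and best_p >= config.acceptable_accuracy:
            label = ActivityLabel.coerce(int(model.classes_[int(np.argmax(best_proba))]))
            events.append(DetectionEvent(
                start=start, end=best_end, label=label,
                probability=best_p, probabilities=best_proba,
            ))
            new_start = best_end
        elif ends.size == 0:
            new_start = start + window
        elif config.reject_advance == "nearest" or ends.size == 1:
            new_start = int(ends[0])
        else:
            new_start = int(ends[-2])
        if new_start <= start:   # safety net: guarantee forward progress
            new_start = start + 1
        logger.debug("advance %d -> %d (%d candidates, best p=%.3f)",
                     start, new_start, ends.size, best_p)
        start = new_start
    return events


def match_events(
    events: list[DetectionEvent],
    segments,
    min_overlap: float = 0.5,
) -> dict:
    """Score detections against ground-truth segments.

    A segment counts as matched when some event carries its label and
    overlaps it by at least ``min_overlap`` of the segment's length; each
    event may match at most one segment. Returns the per-segment match
    flags and the match fraction (recall).
    """
    matched = []
    used: set[int] = set()
    for seg in segments:
        hit = False
        for i, ev in enumerate(events):
            if i in used or ev.label != seg.label:
                continue
            if seg.overlap(ev.start, ev.end) >= min_overlap * seg.length:
                used.add(i)
                hit = True
                break
        matched.append(hit)
    recall = float(np.mean(matched)) if matched else float("nan")
    return {"matched": matched, "recall": recall,
            "n_segments": len(matched), "n_events": len(events)}
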