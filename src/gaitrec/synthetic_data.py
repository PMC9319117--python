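"""Synthetic thigh-IMU gait signals with known ground truth.

Each activity cycle is modeled per channel as a sum of Gaussian lobes
``a * exp(-(t - c*T)^2 / (2*(w*T)^2))`` over the cycle duration ``T``, plus
white measurement noise. The shipped lobe tables are qualitative: they
reproduce the characteristic per-activity structure of thigh-mounted
recordings — sit-to-stand and stand-to-sit are single, opposite-signed
sagittal rotation (G_z) events; walking is a two-lobe swing pattern; stair
climbs/descents resemble walking but with distinctly larger vertical
acceleration lobes — without claiming biomechanical accuracy. Per-cycle
duration draws and ±10% per-channel amplitude jitter emulate stride-length,
step-height and seat-height diversity across recordings.

All randomness flows from explicit integer seeds, so every dataset and
session is bit-reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .activities import ActivityLabel
from .core import GaitCycle, SegmentAnnotation, SessionRecording

#: Token accepted in session scripts for an unannotated rest period.
REST = "rest"

#: Class mix of the five-activity reference benchmark (670 cycles total).
REFERENCE_CLASS_COUNTS: dict[ActivityLabel, int] = {
    ActivityLabel.STANDING_UP: 139,
    ActivityLabel.SITTING_DOWN: 140,
    ActivityLabel.WALKING: 156,
    ActivityLabel.GOING_UPSTAIRS: 122,
    ActivityLabel.GOING_DOWNSTAIRS: 113,
}


@dataclass(frozen=True)
class Lobe:
    """One Gaussian lobe: amplitude in channel units, center and width as
    fractions of the cycle duration."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"lobe width must be positive, got {self.width}")


_CHANNELS = ("ax", "ay", "gz")

# Qualitative per-activity lobe tables (ax, ay in m/s^2; gz in rad/s).
# Sit/stand: one dominant G_z lobe, opposite signs. Stairs: |A_y| lobes
# larger than walking's. Walking: symmetric two-lobe swing.
_DEFAULT_LOBES: dict[ActivityLabel, dict[str, tuple[Lobe, ...]]] = {
    ActivityLabel.STANDING_UP: {
        "ax": (Lobe(1.2, 0.40, 0.15),),
        "ay": (Lobe(1.8, 0.50, 0.20),),
        "gz": (Lobe(2.5, 0.45, 0.18),),
    },
    ActivityLabel.SITTING_DOWN: {
        "ax": (Lobe(-1.0, 0.45, 0.15),),
        "ay": (Lobe(1.5, 0.55, 0.20),),
        "gz": (Lobe(-2.5, 0.50, 0.18),),
    },
    ActivityLabel.WALKING: {
        "ax": (Lobe(2.0, 0.25, 0.08), Lobe(-1.5, 0.65, 0.10)),
        "ay": (Lobe(1.0, 0.30, 0.10), Lobe(0.8, 0.70, 0.10)),
        "gz": (Lobe(1.5, 0.30, 0.12), Lobe(-1.5, 0.75, 0.12)),
    },
    ActivityLabel.GOING_UPSTAIRS: {
        "ax": (Lobe(1.5, 0.30, 0.10), Lobe(-1.0, 0.70, 0.10)),
        "ay": (Lobe(3.0, 0.35, 0.12), Lobe(1.2, 0.75, 0.10)),
        "gz": (Lobe(2.0, 0.25, 0.10), Lobe(-1.2, 0.70, 0.15)),
    },
    ActivityLabel.GOING_DOWNSTAIRS: {
        "ax": (Lobe(-1.2, 0.30, 0.10), Lobe(1.8, 0.60, 0.10)),
        "ay": (Lobe(-2.5, 0.40, 0.12), Lobe(2.0, 0.75, 0.08)),
        "gz": (Lobe(-1.0, 0.30, 0.12), Lobe(1.8, 0.70, 0.10)),
    },
}

# Plausible cycle-duration ranges in seconds (walking strides are quick,
# chair transfers slow).
_DEFAULT_DURATIONS: dict[ActivityLabel, tuple[float, float]] = {
    ActivityLabel.STANDING_UP: (1.5, 3.0),
    ActivityLabel.SITTING_DOWN: (1.5, 3.0),
    ActivityLabel.WALKING: (0.8, 1.6),
    ActivityLabel.GOING_UPSTAIRS: (1.0, 2.0),
    ActivityLabel.GOING_DOWNSTAIRS: (1.0, 2.0),
}


@dataclass
class TemplateParams:
    """Tunable parameters of the synthetic-signal generator.

    noise_sd_acc / noise_sd_gyr are the white-noise standard deviations of
    the accelerometer (m/s^2) and gyroscope (rad/s) channels during
    activity; rest_* apply during rest. amplitude_jitter is the half-width
    of the per-cycle, per-channel multiplicative amplitude perturbation.
    """

    lobes: dict[ActivityLabel, dict[str, tuple[Lobe, ...]]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_LOBES)
    )
    duration_range: dict[ActivityLabel, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DURATIONS)
    )
    noise_sd_acc: float = 0.2
    noise_sd_gyr: float = 0.1
    rest_noise_sd_acc: float = 0.02
    rest_noise_sd_gyr: float = 0.01
    amplitude_jitter: float = 0.10

    def __post_init__(self) -> None:
        for sd in (self.noise_sd_acc, self.noise_sd_gyr,
                   self.rest_noise_sd_acc, self.rest_noise_sd_gyr):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if self.amplitude_jitter < 0:
            raise ValueError("amplitude_jitter must be >= 0")
        for label, (lo, hi) in self.duration_range.items():
            if not (0 < lo <= hi):
                raise ValueError(
                    f"duration range for {label} must be positive and ordered"
                )

    @classmethod
    def default(cls) -> "TemplateParams":
        return cls()

    def noiseless(self) -> "TemplateParams":
        """A copy with all measurement noise switched off (jitter kept)."""
        return replace(
            self,
            lobes=copy.deepcopy(self.lobes),
            duration_range=dict(self.duration_range),
            noise_sd_acc=0.0,
            noise_sd_gyr=0.0,
            rest_noise_sd_acc=0.0,
            rest_noise_sd_gyr=0.0,
        )

    # -- config (de)serialization -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lobes": {
                label.key: {
                    ch: [[lb.amplitude, lb.center, lb.width] for lb in lobe_list]
                    for ch, lobe_list in table.items()
                }
                for label, table in self.lobes.items()
            },
            "duration_range": {
                label.key: list(rng) for label, rng in self.duration_range.items()
            },
            "noise_sd_acc": self.noise_sd_acc,
            "noise_sd_gyr": self.noise_sd_gyr,
            "rest_noise_sd_acc": self.rest_noise_sd_acc,
            "rest_noise_sd_gyr": self.rest_noise_sd_gyr,
            "amplitude_jitter": self.amplitude_jitter,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TemplateParams":
        base = cls.default()
        kwargs: dict = {}
        if "lobes" in data:
            kwargs["lobes"] = {
                ActivityLabel.from_key(key): {
                    ch: tuple(Lobe(*lb) for lb in lobe_list)
                    for ch, lobe_list in table.items()
                }
                for key, table in data["lobes"].items()
            }
        if "duration_range" in data:
            kwargs["duration_range"] = {
                ActivityLabel.from_key(key): tuple(rng)
                for key, rng in data["duration_range"].items()
            }
        for name in ("noise_sd_acc", "noise_sd_gyr", "rest_noise_sd_acc",
                     "rest_noise_sd_gyr", "amplitude_jitter"):
            if name in data:
                kwargs[name] = float(data[name])
        return replace(base, **kwargs)


def template_waveform(
    activity: ActivityLabel, params: TemplateParams, t_frac: np.ndarray
) -> dict[str, np.ndarray]:
    """Noiseless, jitter-free channel templates at cycle fractions t_frac."""
    activity = ActivityLabel.coerce(activity)
    out = {}
    for ch in _CHANNELS:
        sig = np.zeros_like(t_frac, dtype=float)
        for lobe in params.lobes[activity][ch]:
            sig += lobe.amplitude * np.exp(
                -((t_frac - lobe.center) ** 2) / (2.0 * lobe.width ** 2)
            )
        out[ch] = sig
    return out


def generate_cycle(
    activity,
    params: TemplateParams | None = None,
    f_sample: float = 16.0,
    seed: int = 0,
) -> GaitCycle:
    """Generate one labeled activity cycle.

    The seed fixes every random draw (duration, amplitude jitter, noise),
    so identical arguments give bit-identical cycles.
    """
    activity = ActivityLabel.coerce(activity)
    if f_sample <= 0:
        raise ValueError(f"f_sample must be positive, got {f_sample}")
    if params is None:
        params = TemplateParams.default()
    rng = np.random.default_rng(seed)
    lo, hi = params.duration_range[activity]
    duration = rng.uniform(lo, hi)
    n = max(4, int(round(duration * f_sample)))
    # Sample at bin centers so lobe tails are represented symmetrically.
    t_frac = (np.arange(n) + 0.5) / n
    template = template_waveform(activity, params, t_frac)
    channels = {}
    for ch in _CHANNELS:
        jitter = 1.0 + params.amplitude_jitter * rng.uniform(-1.0, 1.0)
        sd = params.noise_sd_acc if ch in ("ax", "ay") else params.noise_sd_gyr
        channels[ch] = template[ch] * jitter + rng.normal(0.0, 1.0, n) * sd
    return GaitCycle(
        ax=channels["ax"], ay=channels["ay"], gz=channels["gz"],
        f_sample=f_sample, label=activity,
    )


def _child_seeds(seed: int, count: int) -> np.ndarray:
    """Deterministic per-item seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(count)


def generate_dataset(
    class_counts: dict,
    params: TemplateParams | None = None,
    f_sample: float = 16.0,
    seed: int = 0,
) -> list[GaitCycle]:
    """Generate a labeled per-cycle dataset with the requested class counts.

    Cycles are emitted grouped by class in L1..L5 code order; per-cycle
    seeds derive deterministically from the master seed.
    """
    counts = {ActivityLabel.coerce(k): int(v) for k, v in class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("class counts must be >= 0")
    total = sum(counts.values())
    seeds = _child_seeds(seed, total)
    cycles: list[GaitCycle] = []
    i = 0
    for label in sorted(counts, key=int):
        for _ in range(counts[label]):
            cycles.append(generate_cycle(label, params, f_sample, int(seeds[i])))
            i += 1
    return cycles


def generate_session(
    script: list,
    params: TemplateParams | None = None,
    f_sample: float = 16.0,
    seed: int = 0,
) -> SessionRecording:
    """Generate a continuous multi-activity recording from a script.

    ``script`` is a list of ``(what, amount)`` items: ``("rest", seconds)``
    inserts an unannotated low-noise rest period, ``(activity, n_cycles)``
    appends that many consecutive activity cycles, each recorded in
    ``segments`` as its own ground-truth interval.
    """
    if not script:
        raise ValueError("session script must be non-empty")
    if params is None:
        params = TemplateParams.default()
    if f_sample <= 0:
        raise ValueError(f"f_sample must be positive, got {f_sample}")
    seeds = iter(_child_seeds(seed, 2 * sum(
        1 if str(w).lower() == REST or w is None else max(1, int(a))
        for w, a in script
    ) + 8))

    parts = {ch: [] for ch in _CHANNELS}
    segments: list[SegmentAnnotation] = []
    pos = 0
    for what, amount in script:
        if what is None or (isinstance(what, str) and what.lower() == REST):
            n = int(round(float(amount) * f_sample))
            if n <= 0:
                continue
            rng = np.random.default_rng(int(next(seeds)))
            parts["ax"].append(rng.normal(0.0, 1.0, n) * params.rest_noise_sd_acc)
            parts["ay"].append(rng.normal(0.0, 1.0, n) * params.rest_noise_sd_acc)
            parts["gz"].append(rng.normal(0.0, 1.0, n) * params.rest_noise_sd_gyr)
            pos += n
        else:
            label = ActivityLabel.coerce(what)
            for _ in range(int(amount)):
                cyc = generate_cycle(label, params, f_sample, int(next(seeds)))
                for ch in _CHANNELS:
                    parts[ch].append(getattr(cyc, ch))
                segments.append(SegmentAnnotation(pos, pos + cyc.n_samples, label))
                pos += cyc.n_samples
    if pos == 0:
        raise ValueError("session script produced no samples")
    ax = np.concatenate(parts["ax"])
    return SessionRecording(
        t=np.arange(len(ax)) / f_sample,
        ax=ax,
        ay=np.concatenate(parts["ay"]),
        gz=np.concatenate(parts["gz"]),
        f_sample=f_sample,
        segments=segments,
    )


def demo_session_script() -> list:
    """A scripted daily-movement sequence: sit-rest, stand up, rest, seven
    walking strides, six stair-ascent steps, rest, six stair-descent steps,
    six walking strides, sit down, rest — 27 annotated activity cycles."""
    return [
        (REST, 2.0),
        (ActivityLabel.STANDING_UP, 1),
        (REST, 3.8),
        (ActivityLabel.WALKING, 7),
        (ActivityLabel.GOING_UPSTAIRS, 6),
        (REST, 2.3),
        (ActivityLabel.GOING_DOWNSTAIRS, 6),
        (ActivityLabel.WALKING, 6),
        (ActivityLabel.SITTING_DOWN, 1),
        (REST, 1.9),
    ]
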