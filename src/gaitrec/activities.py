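"""The five lower-limb activity classes and their fixed integer codes.

The code mapping (L1..L5) is part of the on-disk and in-memory contract:
confusion matrices, model output layers and label files all order classes
by these codes.
"""

from __future__ import annotations

from enum import IntEnum


class UnknownLabelError(ValueError):
    """Raised when a string does not name one of the five activities."""


class ActivityLabel(IntEnum):
    """Lower-limb activity classes, coded L1..L5.

    ==== ================== =========================================
    Code Name               Movement
    ==== ================== =========================================
    1    STANDING_UP        rising from a seat to upright stance
    2    SITTING_DOWN       lowering from stance onto a seat
    3    WALKING            one level-ground stride
    4    GOING_UPSTAIRS     one stair-ascent step
    5    GOING_DOWNSTAIRS   one stair-descent step
    ==== ================== =========================================
    """

    STANDING_UP = 1
    SITTING_DOWN = 2
    WALKING = 3
    GOING_UPSTAIRS = 4
    GOING_DOWNSTAIRS = 5

    @property
    def key(self) -> str:
        """snake_case name used in CSV files and configs."""
        return self.name.lower()

    @classmethod
    def from_key(cls, key: str) -> "ActivityLabel":
        """Parse a snake_case label string; raise UnknownLabelError otherwise."""
        try:
            return cls[str(key).strip().upper()]
        except KeyError:
            raise UnknownLabelError(
                f"unknown activity label: {key!r} "
                f"(expected one of {[a.key for a in cls]})"
            ) from None

    @classmethod
    def coerce(cls, value) -> "ActivityLabel":
        """Accept an ActivityLabel, an integer code, or a snake_case string."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls.from_key(value)
        try:
            return cls(int(value))
        except (ValueError, TypeError):
            raise UnknownLabelError(f"unknown activity label: {value!r}") from None


NUM_LABELS: int = len(ActivityLabel)

#: Class codes in fixed L1..L5 order, as used for confusion-matrix axes.
ALL_LABELS: tuple[ActivityLabel, ...] = tuple(ActivityLabel)
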