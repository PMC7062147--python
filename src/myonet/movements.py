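"""Lower-limb movement classes.

The three activities are the ones a goniometer-instrumented sEMG protocol
records without extra equipment: level-ground walking, sitting with repeated
knee-extension movements, and standing with repeated knee-flexion movements.
The integer encoding (0/1/2) is stable and used everywhere downstream.
"""

from __future__ import annotations

import enum


class MovementClass(enum.IntEnum):
    """The three lower-limb movement classes, with stable integer codes."""

    WALKING = 0
    SITTING_KNEE_EXTENSION = 1
    STANDING_KNEE_FLEXION = 2

    @classmethod
    def from_any(cls, value) -> "MovementClass":
        """Coerce an int, name string, or MovementClass to a MovementClass."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls[value.strip().upper()]
        return cls(int(value))


N_CLASSES = len(MovementClass)
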