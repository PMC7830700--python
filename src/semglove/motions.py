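"""The four recognized hand states and their canonical encoding order.

The glove distinguishes Extension (E), Rest (R), Spherical grip (S) and
Fist (F).  Every vector encoding in the package (classifier outputs,
confusion matrices, pressure tables) uses the fixed canonical ordering
``E, R, S, F``.
"""

from __future__ import annotations

import enum


class Motion(str, enum.Enum):
    """Hand motion label: ``Motion('E')``, ``Motion.REST`` etc."""

    EXTENSION = "E"
    REST = "R"
    SPHERICAL = "S"
    FIST = "F"

    def __str__(self) -> str:  # labels serialize as their single-letter code
        return self.value


#: Canonical ordering used for all vector encodings (class index 0..3).
MOTION_ORDER: tuple[Motion, ...] = (
    Motion.EXTENSION,
    Motion.REST,
    Motion.SPHERICAL,
    Motion.FIST,
)

#: Motion -> class index under the canonical ordering.
MOTION_INDEX: dict[Motion, int] = {m: i for i, m in enumerate(MOTION_ORDER)}


def as_motion(value: "Motion | str") -> Motion:
    """Coerce a single-letter code or Motion into a Motion."""
    if isinstance(value, Motion):
        return value
    return Motion(str(value))
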