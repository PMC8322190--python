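"""Attended-side label conventions shared across the package.

The two-class attention problem is encoded as integers: ``LEFT = 0`` and
``RIGHT = 1``.  "left" is the positive class wherever a confusion matrix is
involved; the accuracy measure is symmetric in the choice.
"""

from __future__ import annotations

import numpy as np

LEFT: int = 0
RIGHT: int = 1

SIDE_NAMES = {LEFT: "left", RIGHT: "right"}
SIDE_CHARS = {LEFT: "L", RIGHT: "R"}

_PARSE = {
    "left": LEFT, "l": LEFT, "0": LEFT, 0: LEFT,
    "right": RIGHT, "r": RIGHT, "1": RIGHT, 1: RIGHT,
}


def parse_side(value) -> int:
    """Normalize a side given as int, 'left'/'right' or 'L'/'R' to LEFT/RIGHT."""
    key = value.lower() if isinstance(value, str) else value
    try:
        return _PARSE[key]
    except KeyError:
        raise ValueError(f"not a valid side: {value!r}") from None


def other_side(side: int) -> int:
    return RIGHT if side == LEFT else LEFT


def labels_to_chars(labels: np.ndarray) -> list[str]:
    return [SIDE_CHARS[int(v)] for v in labels]


def chars_to_labels(chars) -> np.ndarray:
    return np.asarray([parse_side(c) for c in chars], dtype=np.int8)
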