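"""Vertebral level bookkeeping shared across the pipeline.

The thoracolumbar stack runs C7, T1..T12, L1..L5 (18 levels), indexed
cranial -> caudal. All modules address vertebrae by these string labels.
"""

from __future__ import annotations

LEVELS: tuple[str, ...] = (
    "C7",
    *[f"T{i}" for i in range(1, 13)],
    *[f"L{i}" for i in range(1, 6)],
)

N_LEVELS = len(LEVELS)

LEVEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(LEVELS)}

THORACIC = ("C7",) + tuple(f"T{i}" for i in range(1, 13))
LUMBAR = tuple(f"L{i}" for i in range(1, 6))

#: corner keys per view, ordered (superior pair first)
LATERAL_CORNERS = (
    "superior_anterior",
    "superior_posterior",
    "inferior_anterior",
    "inferior_posterior",
)
FRONTAL_CORNERS = (
    "superior_left",
    "superior_right",
    "inferior_left",
    "inferior_right",
)

VIEWS = ("frontal", "lateral")


def corner_keys(view: str) -> tuple[str, ...]:
    if view == "frontal":
        return FRONTAL_CORNERS
    if view == "lateral":
        return LATERAL_CORNERS
    raise ValueError(f"unknown view: {view!r}")
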