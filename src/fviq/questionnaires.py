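"""Scoring of the vDLQI and VitiQoL quality-of-life instruments.

The vDLQI extends the 10-item Dermatology Life Quality Index (items scored
0-3) with four vitiligo-specific questions on the same 0-3 scale, for a total
range of 0-42.  VitiQoL is a vitiligo-specific instrument with 15 items on a
0-6 response scale, range 0-90.  Both are scored as plain item sums; a DLQI
"not relevant" answer is entered as 0, the instrument's standard rule.

Item text is not bundled (the DLQI is copyrighted); responses are supplied as
integer vectors, optionally loaded from CSV/JSON by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .index import percent_change

VDLQI_N_DLQI_ITEMS = 10
VDLQI_N_VITILIGO_ITEMS = 4
VDLQI_ITEM_MAX = 3
VDLQI_MAX = (VDLQI_N_DLQI_ITEMS + VDLQI_N_VITILIGO_ITEMS) * VDLQI_ITEM_MAX  # 42

VITIQOL_N_ITEMS = 15
VITIQOL_ITEM_MAX = 6
VITIQOL_MAX = VITIQOL_N_ITEMS * VITIQOL_ITEM_MAX  # 90


def _validate_items(
    items: Sequence[int], n: int, item_max: int, label: str
) -> tuple[int, ...]:
    items = tuple(items)
    if len(items) != n:
        raise ValidationError(f"{label}: expected {n} items, got {len(items)}")
    for i, v in enumerate(items):
        if int(v) != v or not 0 <= int(v) <= item_max:
            raise ValidationError(
                f"{label}: item {i + 1} must be an integer in "
                f"[0, {item_max}], got {v!r}"
            )
    return tuple(int(v) for v in items)


@dataclass(frozen=True)
class VdlqiResponse:
    """One vDLQI response: 10 DLQI items + 4 vitiligo add-on items, each 0-3."""

    dlqi_items: tuple[int, ...]
    vitiligo_items: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "dlqi_items",
            _validate_items(
                self.dlqi_items, VDLQI_N_DLQI_ITEMS, VDLQI_ITEM_MAX, "DLQI"
            ),
        )
        object.__setattr__(
            self,
            "vitiligo_items",
            _validate_items(
                self.vitiligo_items,
                VDLQI_N_VITILIGO_ITEMS,
                VDLQI_ITEM_MAX,
                "vitiligo add-on",
            ),
        )

    @classmethod
    def from_items(cls, items: Sequence[int]) -> "VdlqiResponse":
        """Build from a flat 14-item vector (DLQI items first)."""
        items = tuple(items)
        if len(items) != VDLQI_N_DLQI_ITEMS + VDLQI_N_VITILIGO_ITEMS:
            raise ValidationError(
                f"vDLQI: expected 14 items, got {len(items)}"
            )
        return cls(items[:VDLQI_N_DLQI_ITEMS], items[VDLQI_N_DLQI_ITEMS:])


@dataclass(frozen=True)
class VitiqolResponse:
    """One VitiQoL response: 15 items, each 0-6."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "items",
            _validate_items(
                self.items, VITIQOL_N_ITEMS, VITIQOL_ITEM_MAX, "VitiQoL"
            ),
        )


def score_vdlqi(resp: VdlqiResponse) -> int:
    """Total vDLQI score: sum of all 14 items, range 0-42."""
    return sum(resp.dlqi_items) + sum(resp.vitiligo_items)


def score_vitiqol(resp: VitiqolResponse) -> int:
    """Total VitiQoL score: sum of all 15 items, range 0-90."""
    return sum(resp.items)


def score_change(before: int, after: int, max_score: int) -> float:
    """Percent score reduction between timepoints (positive = improvement).

    ``max_score`` contextualises the scores (42 for vDLQI, 90 for VitiQoL).
    A baseline of 0 has no defined relative change; report the absolute
    change instead.
    """
    if not 0 <= after <= max_score or not 0 <= before <= max_score:
        raise ValidationError(
            f"scores must lie in [0, {max_score}], got {before} -> {after}"
        )
    if before == 0:
        raise ValidationError(
            "baseline score 0 has no defined percent change; "
            "report the absolute change instead"
        )
    return percent_change(before, after)
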