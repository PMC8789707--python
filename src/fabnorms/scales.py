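"""FAB scale definitions and raw-score computation.

The Frontal Assessment Battery has six items, each scored 0-3.  The total
score (0-18) is complemented by three two-item sub-scales:

* ``FAB1`` — items 1-2, linguistically mediated executive functioning
  (similarities, phonemic verbal fluency);
* ``FAB2`` — items 3-4, planning (Luria motor sequences, conflicting
  instructions);
* ``FAB3`` — items 5-6, inhibition (go-no-go, prehension behavior).

Each sub-scale therefore ranges 0-6 and the three partition the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class ScaleDefinition:
    """A named subset of the six FAB items with its score range."""

    name: str
    item_indices: tuple[int, ...]  # 1-based item numbers
    min_score: int
    max_score: int

    def __post_init__(self) -> None:
        if not self.item_indices:
            raise ValueError(f"scale {self.name!r} has no items")
        if any(i < 1 or i > 6 for i in self.item_indices):
            raise ValueError(f"scale {self.name!r}: item indices must be in 1..6")


FAB_TOTAL = ScaleDefinition("FAB", (1, 2, 3, 4, 5, 6), 0, 18)
FAB1 = ScaleDefinition("FAB1", (1, 2), 0, 6)
FAB2 = ScaleDefinition("FAB2", (3, 4), 0, 6)
FAB3 = ScaleDefinition("FAB3", (5, 6), 0, 6)

#: All scales in reporting order: total first, then the sub-scales.
ALL_SCALES: tuple[ScaleDefinition, ...] = (FAB_TOTAL, FAB1, FAB2, FAB3)
SUBSCALES: tuple[ScaleDefinition, ...] = (FAB1, FAB2, FAB3)

SCALES_BY_NAME = {s.name: s for s in ALL_SCALES}


def scale_scores(items: Sequence[int], scale: ScaleDefinition) -> int:
    """Raw score of ``scale`` for one subject's six item scores.

    ``items`` is the full 6-vector of item scores (0-3 each), in item
    order; the scale picks out its items and sums them.
    """
    if len(items) != 6:
        raise ValueError(f"expected 6 item scores, got {len(items)}")
    for k, v in enumerate(items, start=1):
        if not (0 <= int(v) <= 3) or int(v) != v:
            raise ValueError(f"item {k} score {v!r} outside 0..3")
    return int(sum(int(items[i - 1]) for i in scale.item_indices))


def all_scale_scores(items: Iterable[int]) -> dict[str, int]:
    """Raw scores for the total and the three sub-scales."""
    items = list(items)
    return {s.name: scale_scores(items, s) for s in ALL_SCALES}
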