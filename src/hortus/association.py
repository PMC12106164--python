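"""Linking specimen annotations to plant names by vertical distance.

A handwritten margin annotation is written beside the printed entry it
indexes, so each margin segment is linked to the plant-name segment whose
bounding-box *Top* is nearest its own: the pair minimising
``|top(margin) - top(plant)|``.  Several annotations may legitimately
point at the same entry (a folio can hold several specimens), so the map
is many-to-one.  Header and footer annotations carry their own plant
names and are not distance-linked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .segmentation import Segment, SegmentKind


@dataclass(frozen=True)
class Pair:
    """A margin-annotation-to-plant-name link and its vertical distance."""

    margin_segment_id: str
    plant_segment_id: str
    distance: float
    ambiguous: bool = False


class UnlinkableError(ValueError):
    """Raised when a margin segment has no plant-name candidates."""


def link_margin_to_plant(
    margin: Segment, plants: Sequence[Segment], ambiguity_eps: float = 0.0
) -> Pair:
    """Link one margin annotation to the plant name with the nearest top.

    Ties between equidistant plants break toward the smaller top (the
    earlier entry on the page).  When the two smallest distances differ by
    less than ``ambiguity_eps`` the pair is flagged ambiguous — the
    intersecting-annotation cases that humans also find hard to call.
    """
    if not plants:
        raise UnlinkableError(f"no plant names to link margin {margin.id}")
    for p in plants:
        if p.kind is not SegmentKind.PLANT_NAME:
            raise ValueError(f"candidate {p.id} is {p.kind}, not a plant name")
    x = margin.bbox.top
    best = min(plants, key=lambda p: (abs(x - p.bbox.top), p.bbox.top))
    distances = sorted(abs(x - p.bbox.top) for p in plants)
    ambiguous = (
        ambiguity_eps > 0 and len(distances) > 1 and distances[1] - distances[0] < ambiguity_eps
    )
    return Pair(margin.id, best.id, abs(x - best.bbox.top), ambiguous)


def link_page(
    margins: Sequence[Segment],
    plants: Sequence[Segment],
    ambiguity_eps: float = 0.0,
) -> tuple[list[Pair], list[str]]:
    """Link every margin segment on a page; returns (pairs, unlinked ids).

    Each margin is linked independently, so the result is a function from
    margins to plants (many-to-one allowed), ordered by margin top.  With
    no plant names on the page all margins are reported unlinked.
    """
    pairs: list[Pair] = []
    unlinked: list[str] = []
    for margin in sorted(margins, key=lambda m: m.bbox.top):
        if margin.kind is not SegmentKind.MARGIN:
            raise ValueError(f"segment {margin.id} is {margin.kind}, not a margin")
        if not plants:
            unlinked.append(margin.id)
            continue
        pairs.append(link_margin_to_plant(margin, plants, ambiguity_eps))
    return pairs, unlinked
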