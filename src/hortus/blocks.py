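"""Block-level data model for OCR output and the Textract JSON dialect.

The "DetectDocumentText" dialect represents a scanned page as a flat array
of Block objects.  A PAGE block is the parent of all LINE blocks, and each
LINE block lists its child WORD blocks in a Relationships array.  Every
block carries a fractional bounding box (``Left``/``Top``/``Width``/
``Height`` as ratios of the page raster), WORD blocks additionally carry a
transcription, a PRINTED/HANDWRITING text-type flag and a confidence
percentage.  This module parses that dialect into typed records, writes it
back round-trip stably, and provides the small coordinate utilities the
layout stages build on.
"""

from __future__ import annotations

import json
import logging
import statistics
import uuid
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

logger = logging.getLogger(__name__)

#: Slack for provider rounding of fractional coordinates.
COORD_EPS = 1e-6

#: Raster dimensions assumed when the input does not state them (the
#: digitisation project's scan resolution).
DEFAULT_PAGE_WIDTH_PX = 4992
DEFAULT_PAGE_HEIGHT_PX = 6668


class TextType(str, Enum):
    PRINTED = "PRINTED"
    HANDWRITING = "HANDWRITING"


class BlockParseError(ValueError):
    """Raised when the input is not a well-formed block document."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in page-fraction coordinates, origin top-left.

    ``left`` and ``width`` are fractions of page width, ``top`` and
    ``height`` fractions of page height; boxes are treated as closed
    rectangles.
    """

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.left < -COORD_EPS or self.top < -COORD_EPS:
            raise ValueError(f"box origin out of page: {self}")
        if self.width < 0 or self.height < 0:
            raise ValueError(f"negative box extent: {self}")
        if self.left + self.width > 1 + COORD_EPS or self.top + self.height > 1 + COORD_EPS:
            raise ValueError(f"box exceeds page: {self}")

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @staticmethod
    def hull(boxes: Iterable["BoundingBox"]) -> "BoundingBox":
        """Tight axis-aligned hull of one or more boxes."""
        boxes = list(boxes)
        if not boxes:
            raise ValueError("hull of empty box set")
        left = min(b.left for b in boxes)
        top = min(b.top for b in boxes)
        right = max(b.right for b in boxes)
        bottom = max(b.bottom for b in boxes)
        return BoundingBox(left, top, right - left, bottom - top)


@dataclass(frozen=True)
class WordBlock:
    id: str
    text: str
    text_type: TextType
    bbox: BoundingBox
    confidence: float = 100.0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"word {self.id!r} has empty text")
        if not 0 <= self.confidence <= 100:
            raise ValueError(f"confidence out of range: {self.confidence}")


@dataclass(frozen=True)
class LineBlock:
    id: str
    text: str
    bbox: BoundingBox
    child_word_ids: tuple[str, ...]


@dataclass
class PageBlocks:
    """Parsed OCR output for one page."""

    page_id: str
    lines: list[LineBlock]
    words: dict[str, WordBlock]
    width_px: int = DEFAULT_PAGE_WIDTH_PX
    height_px: int = DEFAULT_PAGE_HEIGHT_PX
    page_bbox: BoundingBox = field(default_factory=lambda: BoundingBox(0, 0, 1, 1))

    def line_words(self, line: LineBlock) -> list[WordBlock]:
        return [self.words[w] for w in line.child_word_ids]

    def validate(self) -> None:
        owner: dict[str, str] = {}
        for line in self.lines:
            for wid in line.child_word_ids:
                if wid not in self.words:
                    raise ValueError(f"line {line.id} references unknown word {wid}")
                if wid in owner:
                    raise ValueError(f"word {wid} claimed by lines {owner[wid]} and {line.id}")
                owner[wid] = line.id
        orphans = set(self.words) - set(owner)
        if orphans:
            raise ValueError(f"words outside any line: {sorted(orphans)}")


def top_fraction(pixel_top: int, page_height: int) -> float:
    """Convert a pixel y-coordinate to a fraction of page height.

    The provider reports box coordinates as ratios of the raster, e.g. a
    top edge at 1500 px on a 6668 px page is the fraction 1500/6668 ≈ 0.22.
    """
    if page_height <= 0:
        raise ValueError(f"page height must be positive, got {page_height}")
    if not 0 <= pixel_top <= page_height:
        raise ValueError(f"pixel top {pixel_top} outside page of height {page_height}")
    return pixel_top / page_height


def word_top_median(page: PageBlocks, line: LineBlock, printed_only: bool = True) -> float:
    """Vertical position of a line from the median of its word-box tops.

    Line boxes on skewed scans are inflated beyond the glyphs, so spacing
    measures use the word boxes, which stay tight.  Printed words are
    preferred; a line with no printed words falls back to all its words.
    """
    words = page.line_words(line)
    tops = [w.bbox.top for w in words if w.text_type is TextType.PRINTED] if printed_only else []
    if not tops:
        tops = [w.bbox.top for w in words]
    if not tops:
        return line.bbox.top
    return statistics.median(tops)


def line_pitch(page: PageBlocks, default: float | None = None) -> float:
    """Median vertical gap between consecutive line tops (word-box based).

    A robust single-page estimate of the body leading; spacing thresholds
    are expressed as multiples of it.  Pages with fewer than two lines have
    no pitch: the configured ``default`` is returned, or an error raised.
    """
    tops = sorted(word_top_median(page, ln) for ln in page.lines)
    gaps = [b - a for a, b in zip(tops, tops[1:]) if b - a > 0]
    if not gaps:
        if default is not None:
            return default
        raise ValueError(f"page {page.page_id}: cannot estimate pitch from {len(page.lines)} line(s)")
    return statistics.median(gaps)


# ---------------------------------------------------------------------------
# Textract dialect reader / writer


def _read_bbox(geometry: dict) -> BoundingBox:
    bb = geometry["BoundingBox"]
    return BoundingBox(
        left=max(0.0, float(bb["Left"])),
        top=max(0.0, float(bb["Top"])),
        width=float(bb["Width"]),
        height=float(bb["Height"]),
    )


def _child_ids(block: dict) -> list[str]:
    ids: list[str] = []
    for rel in block.get("Relationships", []) or []:
        if rel.get("Type") == "CHILD":
            ids.extend(rel.get("Ids", []))
    return ids


def parse_textract_json(raw_json: str) -> list[PageBlocks]:
    """Parse a block document into one :class:`PageBlocks` per PAGE block.

    Both single-page and multi-page Blocks arrays are accepted.  Unknown
    block types are ignored with a warning.  A WORD referenced by no LINE
    is wrapped in a synthetic one-word line so degraded provider output
    still flows through the pipeline.
    """
    try:
        doc = json.loads(raw_json)
    except json.JSONDecodeError as exc:
        raise BlockParseError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "Blocks" not in doc:
        raise BlockParseError("document has no Blocks array")
    blocks = doc["Blocks"]
    if not isinstance(blocks, list):
        raise BlockParseError("Blocks is not an array")

    by_id = {b["Id"]: b for b in blocks if "Id" in b}
    pages: list[PageBlocks] = []
    page_blocks = [b for b in blocks if b.get("BlockType") == "PAGE"]
    if not page_blocks and blocks:
        raise BlockParseError("no PAGE block in non-empty Blocks array")
    if not page_blocks:
        return [PageBlocks(page_id="empty", lines=[], words={})]

    for ordinal, pb in enumerate(page_blocks):
        dims = pb.get("PageDimensions", {})
        width_px = int(dims.get("Width", DEFAULT_PAGE_WIDTH_PX))
        height_px = int(dims.get("Height", DEFAULT_PAGE_HEIGHT_PX))
        page = PageBlocks(
            page_id=str(pb.get("Id", f"page-{ordinal}")),
            lines=[],
            words={},
            width_px=width_px,
            height_px=height_px,
            page_bbox=_read_bbox(pb["Geometry"]) if "Geometry" in pb else BoundingBox(0, 0, 1, 1),
        )

        line_ids = [i for i in _child_ids(pb) if by_id.get(i, {}).get("BlockType") == "LINE"]
        # Pages that omit PAGE->LINE relationships: take LINEs in array order.
        if not line_ids:
            line_ids = [b["Id"] for b in blocks if b.get("BlockType") == "LINE"]

        for lid in line_ids:
            lb = by_id[lid]
            child_ids = []
            for wid in _child_ids(lb):
                wb = by_id.get(wid)
                if wb is None or wb.get("BlockType") != "WORD":
                    logger.warning("line %s references non-WORD child %s; ignored", lid, wid)
                    continue
                page.words[wid] = _parse_word(wb)
                child_ids.append(wid)
            child_ids.sort(key=lambda w: page.words[w].bbox.left)
            page.lines.append(
                LineBlock(
                    id=str(lid),
                    text=lb.get("Text", ""),
                    bbox=_read_bbox(lb["Geometry"]),
                    child_word_ids=tuple(child_ids),
                )
            )

        for b in blocks:
            if b.get("BlockType") == "WORD" and b["Id"] not in page.words and len(page_blocks) == 1:
                logger.warning("orphan WORD %s attached to a synthetic line", b["Id"])
                word = _parse_word(b)
                page.words[word.id] = word
                page.lines.append(
                    LineBlock(
                        id=f"synthetic-line-{word.id}",
                        text=word.text,
                        bbox=word.bbox,
                        child_word_ids=(word.id,),
                    )
                )

        known = {"PAGE", "LINE", "WORD"}
        for b in blocks:
            if b.get("BlockType") not in known:
                logger.warning("ignoring unknown block type %r", b.get("BlockType"))
        page.lines.sort(key=lambda ln: (ln.bbox.top, ln.bbox.left))
        pages.append(page)
    return pages


def parse_single_page(raw_json: str) -> PageBlocks:
    """Parse a document expected to hold exactly one page."""
    pages = parse_textract_json(raw_json)
    if len(pages) != 1:
        raise BlockParseError(f"expected one page, found {len(pages)}")
    return pages[0]


def _parse_word(block: dict) -> WordBlock:
    return WordBlock(
        id=str(block["Id"]),
        text=block["Text"],
        text_type=TextType(block.get("TextType", "PRINTED")),
        bbox=_read_bbox(block["Geometry"]),
        confidence=float(block.get("Confidence", 100.0)),
    )


def _bbox_json(b: BoundingBox) -> dict:
    return {
        "BoundingBox": {"Left": b.left, "Top": b.top, "Width": b.width, "Height": b.height}
    }


def write_blocks(page: PageBlocks) -> str:
    """Serialise a page back to the block dialect; round-trip stable."""
    page.validate()
    blocks: list[dict] = []
    page_block: dict = {
        "BlockType": "PAGE",
        "Id": page.page_id,
        "Geometry": _bbox_json(page.page_bbox),
        "PageDimensions": {"Width": page.width_px, "Height": page.height_px},
    }
    if page.lines:
        page_block["Relationships"] = [{"Type": "CHILD", "Ids": [ln.id for ln in page.lines]}]
    blocks.append(page_block)
    for line in page.lines:
        lb: dict = {
            "BlockType": "LINE",
            "Id": line.id,
            "Text": line.text,
            "Geometry": _bbox_json(line.bbox),
        }
        if line.child_word_ids:
            lb["Relationships"] = [{"Type": "CHILD", "Ids": list(line.child_word_ids)}]
        blocks.append(lb)
        for wid in line.child_word_ids:
            w = page.words[wid]
            blocks.append(
                {
                    "BlockType": "WORD",
                    "Id": w.id,
                    "Text": w.text,
                    "TextType": w.text_type.value,
                    "Confidence": w.confidence,
                    "Geometry": _bbox_json(w.bbox),
                }
            )
    return json.dumps({"Blocks": blocks}, indent=1, sort_keys=True)


def new_id() -> str:
    return str(uuid.uuid4())
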