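"""Segment detection: paragraphs, plant names, margins, headers, footers.

Paragraph boundaries are found from vertical spacing, measured on the
word-level boxes rather than the provider's line boxes: skewed scans
inflate line boxes and corrupt the spacing signal, while the word boxes
stay tight on the glyphs.  Handwritten interruptions inside the printed
body are discounted from the spacing measure, so an annotation scribbled
between two lines of a paragraph does not split it.  Printed plant-name
entries are recognised by indentation with typographic fallbacks; the
handwritten bands are split into annotation segments on the specimen
initials ("H.S.") and on spacing.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .blocks import BoundingBox, LineBlock, PageBlocks, TextType, word_top_median
from .config import PipelineConfig


class SegmentKind(str, Enum):
    HEADER = "HEADER"
    FOOTER = "FOOTER"
    MARGIN = "MARGIN"
    PLANT_NAME = "PLANT_NAME"
    PARAGRAPH = "PARAGRAPH"


@dataclass
class Segment:
    """A typed page region: the tight hull of its member words."""

    id: str
    kind: SegmentKind
    bbox: BoundingBox
    text: str
    word_ids: list[str]
    line_ids: list[str]
    handwritten_word_ids: list[str] = field(default_factory=list)

    @property
    def top(self) -> float:
        return self.bbox.top


@dataclass(frozen=True)
class SpecimenReference:
    """A parsed 'H.S. <volume> <folio> [<specimen>]' herbarium reference."""

    volume: int
    folio: int
    specimen: int | None = None


def _line_is_handwritten(page: PageBlocks, line: LineBlock) -> bool:
    words = page.line_words(line)
    if not words:
        return False
    hand = sum(1 for w in words if w.text_type is TextType.HANDWRITING)
    return hand > len(words) / 2


def _line_top(page: PageBlocks, line: LineBlock, cfg: PipelineConfig) -> float:
    if cfg.use_line_boxes:
        return line.bbox.top
    return word_top_median(page, line)


def _make_segment(
    page: PageBlocks, kind: SegmentKind, lines: Sequence[LineBlock], seg_id: str
) -> Segment:
    words = [w for ln in lines for w in page.line_words(ln)]
    bbox = BoundingBox.hull([w.bbox for w in words]) if words else lines[0].bbox
    return Segment(
        id=seg_id,
        kind=kind,
        bbox=bbox,
        text=" ".join(ln.text for ln in lines),
        word_ids=[w.id for w in words],
        line_ids=[ln.id for ln in lines],
        handwritten_word_ids=[w.id for w in words if w.text_type is TextType.HANDWRITING],
    )


def segment_paragraphs(
    page: PageBlocks,
    body_lines: Sequence[LineBlock],
    pitch: float,
    cfg: PipelineConfig | None = None,
    id_prefix: str = "",
) -> list[Segment]:
    """Group body lines into paragraph segments by word-level spacing.

    A new paragraph opens when the gap between consecutive printed lines
    exceeds ``para_gap_mult x pitch``, after subtracting the box heights of
    any handwritten lines sitting in the gap (they occupy space without
    being part of the printed flow).  Handwritten-only lines are attached
    to the paragraph they interrupt, with their words flagged.
    """
    cfg = cfg or PipelineConfig()
    if not body_lines:
        return []
    ordered = sorted(body_lines, key=lambda ln: _line_top(page, ln, cfg))
    threshold = cfg.para_gap_mult * pitch

    groups: list[list[LineBlock]] = []
    current: list[LineBlock] = []
    pending_hand: list[LineBlock] = []  # handwritten lines before any printed line
    prev_printed_top: float | None = None
    hand_between: float = 0.0  # vertical extent of handwriting since last printed line

    for line in ordered:
        if _line_is_handwritten(page, line):
            if current:
                current.append(line)
            else:
                pending_hand.append(line)
            hand_between += line.bbox.height
            continue
        top = _line_top(page, line, cfg)
        if prev_printed_top is None:
            current = pending_hand + [line]
            pending_hand = []
        else:
            gap = top - prev_printed_top - hand_between
            if gap > threshold:
                groups.append(current)
                current = [line]
            else:
                current.append(line)
        prev_printed_top = top
        hand_between = 0.0
    if pending_hand and not current:
        current = pending_hand
    elif pending_hand:
        current.extend(pending_hand)
    if current:
        groups.append(current)

    return [
        _make_segment(page, SegmentKind.PARAGRAPH, grp, f"{id_prefix}paragraph:{i}")
        for i, grp in enumerate(groups)
    ]


@dataclass(frozen=True)
class BodyContext:
    """Page-level features consulted by the plant-name classifier."""

    body_left: float  # left edge of the printed body envelope
    pitch: float


def body_context(page: PageBlocks, body_lines: Sequence[LineBlock], pitch: float) -> BodyContext:
    lefts = [
        w.bbox.left
        for ln in body_lines
        for w in page.line_words(ln)
        if w.text_type is TextType.PRINTED
    ]
    return BodyContext(body_left=min(lefts) if lefts else 0.0, pitch=pitch)


def classify_plant_name(
    page: PageBlocks, seg: Segment, context: BodyContext, cfg: PipelineConfig | None = None
) -> bool:
    """Decide whether a paragraph segment is a printed plant-name entry.

    Primary evidence is typographic: entries are indented relative to the
    body-left envelope and short.  Entries set flush with the text fall
    back on lexical features: an opening author abbreviation, a capitalised
    first character on a short segment, or all-uppercase words.
    """
    cfg = cfg or PipelineConfig()
    if seg.kind is not SegmentKind.PARAGRAPH:
        raise ValueError("plant-name classification applies to paragraph segments")
    printed_words = [
        page.words[w] for w in seg.word_ids if page.words[w].text_type is TextType.PRINTED
    ]
    if not printed_words:
        return False
    n_lines = _printed_line_count(page, seg)
    first_word = min(printed_words, key=lambda w: (w.bbox.top, w.bbox.left))
    indent = first_word.bbox.left - context.body_left

    if indent > cfg.indent_frac and n_lines <= cfg.max_name_lines:
        return True
    first_token = first_word.text
    if any(first_token.rstrip(".") == abbr.rstrip(".") for abbr in cfg.abbreviation_lexicon):
        return True
    if first_token[:1].isupper() and n_lines <= cfg.max_capital_lines:
        return True
    if all(w.text.isupper() for w in printed_words):
        return True
    return False


def _printed_line_count(page: PageBlocks, seg: Segment) -> int:
    by_id = {ln.id: ln for ln in page.lines}
    return sum(
        1
        for lid in seg.line_ids
        if lid in by_id and not _line_is_handwritten(page, by_id[lid])
    )


def split_plant_names(
    page: PageBlocks,
    paragraphs: Sequence[Segment],
    context: BodyContext,
    cfg: PipelineConfig | None = None,
    id_prefix: str = "",
) -> tuple[list[Segment], list[Segment]]:
    """Partition paragraph segments into plant names and prose paragraphs."""
    cfg = cfg or PipelineConfig()
    plants: list[Segment] = []
    prose: list[Segment] = []
    for seg in sorted(paragraphs, key=lambda s: s.top):
        if classify_plant_name(page, seg, context, cfg):
            seg.kind = SegmentKind.PLANT_NAME
            seg.id = f"{id_prefix}plant:{len(plants)}"
            plants.append(seg)
        else:
            seg.id = f"{id_prefix}paragraph:{len(prose)}"
            prose.append(seg)
    return plants, prose


def _gap_groups(
    page: PageBlocks,
    lines: Sequence[LineBlock],
    pitch: float,
    cfg: PipelineConfig,
    new_segment_pred=None,
) -> list[list[LineBlock]]:
    """Group lines top-to-bottom, breaking on wide gaps or a predicate."""
    ordered = sorted(lines, key=lambda ln: _line_top(page, ln, cfg))
    threshold = cfg.margin_gap_mult * pitch
    groups: list[list[LineBlock]] = []
    prev_top: float | None = None
    for line in ordered:
        top = _line_top(page, line, cfg)
        starts_new = new_segment_pred(line) if new_segment_pred else False
        if not groups or starts_new or (prev_top is not None and top - prev_top > threshold):
            groups.append([line])
        else:
            groups[-1].append(line)
        prev_top = top
    return groups


def segment_margins(
    page: PageBlocks,
    margin_lines: Sequence[LineBlock],
    pitch: float,
    cfg: PipelineConfig | None = None,
    id_prefix: str = "",
) -> list[Segment]:
    """Split side-margin lines into specimen-annotation segments.

    A new segment opens at any line starting with the specimen initials
    ("H.S.", tolerating spacing and punctuation variants) and at any gap
    wider than ``margin_gap_mult x pitch``; continuation lines of folio
    numbers stay attached to their opening line.
    """
    cfg = cfg or PipelineConfig()
    if not margin_lines:
        return []
    hs_re = re.compile(cfg.hs_pattern, re.IGNORECASE)
    groups = _gap_groups(
        page, margin_lines, pitch, cfg, new_segment_pred=lambda ln: bool(hs_re.match(ln.text))
    )
    return [
        _make_segment(page, SegmentKind.MARGIN, grp, f"{id_prefix}margin:{i}")
        for i, grp in enumerate(groups)
    ]


def segment_headers_footers(
    page: PageBlocks,
    header_lines: Sequence[LineBlock],
    footer_lines: Sequence[LineBlock],
    pitch: float,
    cfg: PipelineConfig | None = None,
    id_prefix: str = "",
) -> list[Segment]:
    """Group handwritten band lines into header/footer annotation segments.

    Printed lines in the bands (the running title, page numbers) carry no
    annotations and are excluded; the remaining handwritten lines are
    grouped by the same gap rule as the margins.
    """
    cfg = cfg or PipelineConfig()
    out: list[Segment] = []
    for kind, lines in ((SegmentKind.HEADER, header_lines), (SegmentKind.FOOTER, footer_lines)):
        hand = [ln for ln in lines if _line_is_handwritten(page, ln)]
        if not hand:
            continue
        groups = _gap_groups(page, hand, pitch, cfg)
        out.extend(
            _make_segment(page, kind, grp, f"{id_prefix}{kind.value.lower()}:{i}")
            for i, grp in enumerate(groups)
        )
    return out


# Specimen references: "H.S. <volume> <folio> [<specimen>]".  The folio is
# sometimes prefixed with "p." in the hand; separators vary between dots
# and spaces.
_HS_ANCHOR = re.compile(r"H\s*\.?\s*S\s*\.?", re.IGNORECASE)
_NUMBER = re.compile(r"(?:p\s*\.?\s*)?(\d+)", re.IGNORECASE)


def parse_specimen_reference(text: str) -> tuple[list[SpecimenReference], str]:
    """Best-effort extraction of specimen references from a transcription.

    Each "H.S." anchor opens a reference; the next two numbers are volume
    and folio (the folio may carry a "p." prefix) and a third, when
    present before the next anchor, is the specimen position on the folio.
    Unconsumed spans are returned as the residue.  Never raises: degraded
    handwriting transcriptions are expected.
    """
    refs: list[SpecimenReference] = []
    consumed: list[tuple[int, int]] = []
    anchors = list(_HS_ANCHOR.finditer(text))
    for i, anchor in enumerate(anchors):
        start = anchor.end()
        end = anchors[i + 1].start() if i + 1 < len(anchors) else len(text)
        numbers = list(_NUMBER.finditer(text, start, end))
        if len(numbers) < 2:
            continue
        volume = int(numbers[0].group(1))
        folio = int(numbers[1].group(1))
        specimen = int(numbers[2].group(1)) if len(numbers) >= 3 else None
        refs.append(SpecimenReference(volume, folio, specimen))
        last = numbers[2] if len(numbers) >= 3 else numbers[1]
        consumed.append((anchor.start(), last.end()))
    residue_parts: list[str] = []
    pos = 0
    for lo, hi in consumed:
        residue_parts.append(text[pos:lo])
        pos = hi
    residue_parts.append(text[pos:])
    residue = " ".join(p.strip(" .,") for p in residue_parts if p.strip(" .,"))
    return refs, residue
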