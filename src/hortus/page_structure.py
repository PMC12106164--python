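"""Page-structure detection.

Odd and even pages of the volumes differ in running title and in which
side carries the handwritten specimen margin, so the first step classifies
page parity from a fuzzy match against the running titles.  The second
step partitions the page's lines into header band, footer band, side
margin, body, and discarded bleed from the adjacent page, using only the
block geometry — no pixel-level processing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import edlib

from .blocks import BoundingBox, LineBlock, PageBlocks, word_top_median
from .config import PipelineConfig, TitlePattern


class Parity(str, Enum):
    ODD = "ODD"
    EVEN = "EVEN"
    UNKNOWN = "UNKNOWN"


class LayoutError(ValueError):
    """Raised when a page is structurally unusable (e.g. empty)."""


@dataclass(frozen=True)
class PageGroup:
    value: Parity
    matched_text: str = ""
    matched_line_id: str = ""


@dataclass
class PageLayout:
    """The five-way partition of a page's lines plus band geometry."""

    header_band: tuple[float, float]
    footer_band: tuple[float, float]
    margin_boundary_x: float
    margin_side: str  # "LEFT" | "RIGHT"
    body_region: BoundingBox
    header_line_ids: list[str] = field(default_factory=list)
    footer_line_ids: list[str] = field(default_factory=list)
    margin_line_ids: list[str] = field(default_factory=list)
    body_line_ids: list[str] = field(default_factory=list)
    discarded_line_ids: list[str] = field(default_factory=list)

    def all_assigned(self) -> list[str]:
        return (
            self.header_line_ids
            + self.footer_line_ids
            + self.margin_line_ids
            + self.body_line_ids
            + self.discarded_line_ids
        )


_CONFUSION = str.maketrans({"1": "I", "0": "O", "|": "I", "!": "I"})


def normalise_title(text: str) -> str:
    """Uppercase, fold digit/letter OCR confusions, strip non-letters."""
    text = text.upper().translate(_CONFUSION)
    return re.sub(r"[^A-Z]", "", text)


def _title_matches(line_text: str, pattern: TitlePattern) -> bool:
    norm_line = normalise_title(line_text)
    norm_pat = normalise_title(pattern.pattern)
    if not norm_line or not norm_pat:
        return False
    # Infix alignment: the title may share its line with a page number.
    res = edlib.align(norm_pat, norm_line, mode="HW", task="distance")
    return res["editDistance"] >= 0 and res["editDistance"] <= pattern.max_edits


def classify_page_group(page: PageBlocks, cfg: PipelineConfig | None = None) -> PageGroup:
    """Classify page parity from running-title evidence.

    Printed lines in the top band of the page are fuzzy-matched against the
    per-parity title patterns; OCR confusions (``H1STORIA``, ``H IST OR1A``,
    ``H I S T O R I A``) are tolerated by normalisation plus a small edit
    budget.  The parity of the first matching line wins; a page with no
    matching title is UNKNOWN.
    """
    cfg = cfg or PipelineConfig()
    candidates = sorted(
        (ln for ln in page.lines if ln.bbox.top < cfg.title_band_frac),
        key=lambda ln: ln.bbox.top,
    )
    for line in candidates:
        for pattern in cfg.title_patterns:
            if _title_matches(line.text, pattern):
                return PageGroup(Parity(pattern.parity), line.text, line.id)
    return PageGroup(Parity.UNKNOWN)


def _margin_side_for(group: PageGroup, cfg: PipelineConfig) -> str:
    even_side = cfg.even_margin_side.upper()
    odd_side = "RIGHT" if even_side == "LEFT" else "LEFT"
    if group.value is Parity.ODD:
        return odd_side
    return even_side  # EVEN and UNKNOWN default to the even-page side


def _x_cover(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of x-intervals, as a sorted list of disjoint segments."""
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def detect_margin_boundary(
    page: PageBlocks, group: PageGroup, cfg: PipelineConfig | None = None
) -> tuple[float, str]:
    """Locate the x-boundary between the side margin and the body.

    The x-intervals of all mid-page words are merged into covered segments;
    the largest uncovered gap on the parity-implied margin side, if wider
    than ``cfg.min_margin_gap``, separates the margin cluster from the body
    envelope and the boundary is placed at its midpoint.  With no such gap
    the boundary collapses onto the body envelope edge (no margin words).
    """
    cfg = cfg or PipelineConfig()
    if not page.lines:
        raise LayoutError(f"page {page.page_id} has no lines")
    side = _margin_side_for(group, cfg)

    # Header/footer bands span the full width (titles, page numbers) and
    # would bridge the margin gap, so only mid-page words are considered.
    intervals = [
        (w.bbox.left, w.bbox.right)
        for ln in page.lines
        if cfg.header_frac <= word_top_median(page, ln) <= cfg.footer_frac
        for w in page.line_words(ln)
    ]
    if not intervals:
        intervals = [(w.bbox.left, w.bbox.right) for ln in page.lines for w in page.line_words(ln)]
    if not intervals:
        raise LayoutError(f"page {page.page_id} has no words")

    cover = _x_cover(intervals)
    gaps = [
        (cover[i + 1][0] - cover[i][1], cover[i][1], cover[i + 1][0])
        for i in range(len(cover) - 1)
    ]
    # Restrict to gaps on the margin half of the page.
    half = 0.5
    if side == "LEFT":
        gaps = [g for g in gaps if (g[1] + g[2]) / 2 < half]
    else:
        gaps = [g for g in gaps if (g[1] + g[2]) / 2 >= half]
    gaps = [g for g in gaps if g[0] > cfg.min_margin_gap]
    if gaps:
        width, lo, hi = max(gaps)
        return (lo + hi) / 2, side
    # No separated cluster: boundary at the body envelope edge.
    if side == "LEFT":
        return cover[0][0], side
    return cover[-1][1], side


def detect_layout(
    page: PageBlocks, group: PageGroup, cfg: PipelineConfig | None = None
) -> PageLayout:
    """Partition every line of the page into exactly one layout class.

    Header: the running-title line and anything above ``header_frac``.
    Footer: lines below ``footer_frac``.  Margin: lines whose words lie
    beyond the margin boundary on the margin side.  Bleed: lines lying
    entirely outside the body envelope on the non-margin side (text from
    the adjacent page caught by the scan), recorded in
    ``discarded_line_ids``.  Everything else is body.
    """
    cfg = cfg or PipelineConfig()
    if not page.lines:
        raise LayoutError(f"page {page.page_id} has no lines")

    boundary, side = detect_margin_boundary(page, group, cfg)

    header_ids: list[str] = []
    footer_ids: list[str] = []
    margin_ids: list[str] = []
    body_ids: list[str] = []
    discarded_ids: list[str] = []

    def is_margin(line: LineBlock) -> bool:
        words = page.line_words(line)
        if not words:
            return False
        if side == "LEFT":
            inside = [w for w in words if w.bbox.right <= boundary]
        else:
            inside = [w for w in words if w.bbox.left >= boundary]
        return len(inside) > len(words) / 2

    # Body x-envelope from mid-page non-margin words, for bleed detection.
    mid_lines = [
        ln
        for ln in page.lines
        if cfg.header_frac <= word_top_median(page, ln) <= cfg.footer_frac and not is_margin(ln)
    ]
    env_words = [w for ln in mid_lines for w in page.line_words(ln)]
    if env_words:
        env_left = min(w.bbox.left for w in env_words)
        env_right = max(w.bbox.right for w in env_words)
    else:
        env_left, env_right = 0.0, 1.0
    # The envelope of mid-page lines still contains any bleed words; shrink
    # it to the dominant mass by dropping lines fully beyond the bleed
    # threshold from the rest.
    if mid_lines:
        if side == "LEFT":
            inner = [
                ln for ln in mid_lines
                if ln.bbox.left < _dominant_edge(mid_lines, outer="right", frac=cfg.bleed_frac)
            ]
            if inner:
                env_right = max(w.bbox.right for ln in inner for w in page.line_words(ln))
        else:
            inner = [
                ln for ln in mid_lines
                if ln.bbox.right > _dominant_edge(mid_lines, outer="left", frac=cfg.bleed_frac)
            ]
            if inner:
                env_left = min(w.bbox.left for ln in inner for w in page.line_words(ln))

    title_line_id = group.matched_line_id
    for line in page.lines:
        top = word_top_median(page, line)
        if line.id == title_line_id or top < cfg.header_frac:
            header_ids.append(line.id)
        elif top > cfg.footer_frac:
            footer_ids.append(line.id)
        elif is_margin(line):
            margin_ids.append(line.id)
        elif side == "LEFT" and line.bbox.left > env_right + cfg.bleed_frac:
            discarded_ids.append(line.id)
        elif side == "RIGHT" and line.bbox.right < env_left - cfg.bleed_frac:
            discarded_ids.append(line.id)
        else:
            body_ids.append(line.id)

    by_id = {ln.id: ln for ln in page.lines}
    body_lines = [by_id[i] for i in body_ids]
    if body_lines:
        body_region = BoundingBox.hull(ln.bbox for ln in body_lines)
    else:
        body_region = BoundingBox(0, cfg.header_frac, 1, max(cfg.footer_frac - cfg.header_frac, 0))

    return PageLayout(
        header_band=(0.0, cfg.header_frac),
        footer_band=(cfg.footer_frac, 1.0),
        margin_boundary_x=boundary,
        margin_side=side,
        body_region=body_region,
        header_line_ids=header_ids,
        footer_line_ids=footer_ids,
        margin_line_ids=margin_ids,
        body_line_ids=body_ids,
        discarded_line_ids=discarded_ids,
    )


def _dominant_edge(lines: list[LineBlock], outer: str, frac: float) -> float:
    """Edge of the dominant text mass, past which isolated lines are bleed.

    Uses the widest covered x-segment of the line boxes as the dominant
    mass and returns its outer edge plus the bleed slack.
    """
    cover = _x_cover([(ln.bbox.left, ln.bbox.right) for ln in lines])
    widest = max(cover, key=lambda seg: seg[1] - seg[0])
    if outer == "right":
        return widest[1] + frac
    return widest[0] - frac
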