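"""Seeded generator of synthetic pages in the OCR block dialect.

Emulates the layout of a two-page-parity printed herbal index: a running
title per parity, body paragraphs with indented printed plant-name
entries, a handwritten specimen margin ("H.S. <volume>. <folio>.") on the
outer side, handwritten annotations in the header and footer bands, bleed
words from the adjacent page, skew-inflated line boxes, handwritten
interruptions inside paragraphs, and per-character transcription noise.
Every page is emitted together with its exact ground truth (segments,
links, layout, clean texts), so each pipeline stage can be scored against
a known answer.  Generation is fully deterministic under the spec's seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .blocks import (
    BoundingBox,
    LineBlock,
    PageBlocks,
    TextType,
    WordBlock,
    write_blocks,
)
from .page_structure import PageLayout, Parity
from .segmentation import Segment, SegmentKind


class GenerationError(ValueError):
    """Raised when a page spec does not fit on the page."""


@dataclass(frozen=True)
class SyntheticPageSpec:
    """Parameters of one synthetic page.

    Rates are probabilities in [0, 1]; vertical quantities are fractions
    of page height.  ``skew_inflation`` adds up to that amount to each
    line-box height (keeping word boxes tight), mimicking the inflated
    line boxes that skewed scans produce.
    """

    seed: int = 0
    parity: Parity = Parity.EVEN
    n_plant_entries: int = 4
    n_margin_annotations: int = 3
    n_header_annotations: int = 1
    n_footer_annotations: int = 1
    paragraph_length_range: tuple[int, int] = (3, 6)
    line_pitch: float = 0.015
    skew_inflation: float = 0.0
    handwritten_interruption_rate: float = 0.0
    bleed_word_count: int = 0
    char_noise_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("skew_inflation", "handwritten_interruption_rate", "char_noise_rate"):
            v = getattr(self, name)
            if not 0 <= v <= (1 if name != "skew_inflation" else 1):
                raise ValueError(f"{name} out of range: {v}")
        if min(self.n_plant_entries, self.n_margin_annotations, self.bleed_word_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.line_pitch <= 0:
            raise ValueError("line pitch must be positive")


@dataclass
class GroundTruth:
    """Exact answer key for one generated page."""

    page_id: str
    group: Parity
    layout: PageLayout
    segments: list[Segment]
    pairs: list[tuple[str, str]]  # (margin segment id, plant segment id)
    clean_texts: dict[str, str] = field(default_factory=dict)

    def segments_of(self, kind: SegmentKind) -> list[Segment]:
        return [s for s in self.segments if s.kind is kind]


# Pre-Linnaean-style polynomial phrases for plant-name entries; only the
# casing and geometry matter to the pipeline, not the botany.
PLANT_NAME_LEXICON = (
    "Corymbiferis flore albo vulgaris",
    "Medica magna turbinata",
    "Gramen pratense paniculatum minus",
    "Absinthium ponticum tenuifolium",
    "Salvia latifolia serrata hispanica",
    "Trifolium pratense purpureum majus",
    "Ranunculus palustris apii folio",
    "Campanula persicifolia caerulea",
    "Eryngium maritimum vulgare",
    "Lysimachia lutea salicariae folio",
)

BODY_LEXICON = (
    "foliis", "caule", "radice", "floribus", "minor", "vulgaris", "pratensis",
    "albo", "purpureo", "semine", "odore", "sapore", "crescit", "locis",
    "humidis", "montibus", "pedalis", "ramosa", "hirsuta", "glabra", "annua",
    "perennis", "iunio", "iulio", "floret", "caulibus", "tenuibus", "serratis",
)

HAND_NOTE_LEXICON = (
    "Chamaedrys spuria minor",
    "Veronica mas supina",
    "Alsine media minor",
    "Polygonum latifolium",
)

# Geometry constants (page fractions).  The margin sits on the outer side:
# left on even pages, right on odd pages; bleed appears at the gutter side.
_TITLE_TOP = 0.022
_HEADER_NOTE_TOP = 0.004
_BODY_TOP = 0.12
_BODY_BOTTOM = 0.91
_FOOTER_NOTE_TOP = 0.930
_PAGE_NUMBER_TOP = 0.955
_WORD_HEIGHT = 0.011
_CHAR_W = 0.0055
_SPACE_W = 0.004
_NOISE_ALPHABET = "abcdefghijklmnopqrstuvwxyz0123456789"


def _geometry(parity: Parity) -> dict:
    if parity is Parity.EVEN:
        return {
            "margin_x": (0.04, 0.145),
            "body_x": (0.18, 0.88),
            "bleed_x": (0.965, 0.995),
            "side": "LEFT",
        }
    return {
        "margin_x": (0.855, 0.96),
        "body_x": (0.12, 0.82),
        "bleed_x": (0.005, 0.035),
        "side": "RIGHT",
    }


class _PageBuilder:
    def __init__(self, page_id: str, rng: random.Random, noise_rate: float) -> None:
        self.page_id = page_id
        self.rng = rng
        self.noise_rate = noise_rate
        self.lines: list[LineBlock] = []
        self.words: dict[str, WordBlock] = {}
        self.clean_line_texts: dict[str, str] = {}
        self._wc = 0
        self._lc = 0

    def _noisy(self, text: str) -> str:
        if self.noise_rate <= 0:
            return text
        out = []
        for ch in text:
            if self.rng.random() < self.noise_rate:
                repl = ch
                while repl == ch:
                    repl = self.rng.choice(_NOISE_ALPHABET)
                out.append(repl)
            else:
                out.append(ch)
        return "".join(out)

    def add_line(
        self,
        tokens: list[str],
        x0: float,
        top: float,
        text_type: TextType,
        skew: float = 0.0,
        x_limit: float = 1.0,
    ) -> LineBlock:
        """Lay tokens left-to-right from ``x0``; returns the new line."""
        word_ids: list[str] = []
        clean_parts: list[str] = []
        noisy_parts: list[str] = []
        x = x0
        for token in tokens:
            width = len(token) * _CHAR_W
            if x + width > x_limit:
                break
            noisy = self._noisy(token)
            wid = f"{self.page_id}:w{self._wc}"
            self._wc += 1
            self.words[wid] = WordBlock(
                id=wid,
                text=noisy,
                text_type=text_type,
                bbox=BoundingBox(x, top, width, _WORD_HEIGHT),
                confidence=99.0,
            )
            word_ids.append(wid)
            clean_parts.append(token)
            noisy_parts.append(noisy)
            x += width + _SPACE_W
        if not word_ids:
            raise GenerationError(f"no token fits in line at x={x0:.3f}")
        hull = BoundingBox.hull([self.words[w].bbox for w in word_ids])
        # Skew inflation stretches the provider line box upward beyond the
        # glyphs; word boxes stay tight.
        delta = self.rng.uniform(0.0, skew) if skew > 0 else 0.0
        line_top = max(0.0, hull.top - delta)
        line_box = BoundingBox(hull.left, line_top, hull.width, hull.bottom - line_top)
        lid = f"{self.page_id}:l{self._lc}"
        self._lc += 1
        line = LineBlock(
            id=lid,
            text=" ".join(noisy_parts),
            bbox=line_box,
            child_word_ids=tuple(word_ids),
        )
        self.lines.append(line)
        self.clean_line_texts[lid] = " ".join(clean_parts)
        return line

    def build(self) -> PageBlocks:
        self.lines.sort(key=lambda ln: (ln.bbox.top, ln.bbox.left))
        page = PageBlocks(page_id=self.page_id, lines=self.lines, words=dict(self.words))
        page.validate()
        return page


def _fill_body_line(rng: random.Random, x0: float, x1: float) -> list[str]:
    tokens = []
    x = x0
    while True:
        token = rng.choice(BODY_LEXICON)
        width = len(token) * _CHAR_W
        if x + width > x1:
            break
        tokens.append(token)
        x += width + _SPACE_W
    return tokens or [rng.choice(BODY_LEXICON)]


def generate_page(spec: SyntheticPageSpec) -> tuple[PageBlocks, GroundTruth]:
    """Generate one page and its exact ground truth; deterministic per spec."""
    rng = random.Random(spec.seed)
    geo = _geometry(spec.parity)
    page_id = f"page-{spec.seed:06d}-{spec.parity.value.lower()}"
    builder = _PageBuilder(page_id, rng, spec.char_noise_rate)
    p = spec.line_pitch
    body_x0, body_x1 = geo["body_x"]
    margin_x0, margin_x1 = geo["margin_x"]

    segments: list[Segment] = []
    clean_texts: dict[str, str] = {}
    header_ids: list[str] = []
    footer_ids: list[str] = []
    margin_line_ids: list[str] = []
    body_line_ids: list[str] = []
    discarded_ids: list[str] = []

    def record_segment(kind: SegmentKind, lines: list[LineBlock], ordinal: int) -> Segment:
        words = [builder.words[w] for ln in lines for w in ln.child_word_ids]
        seg = Segment(
            id=f"{page_id}:gt:{kind.value.lower()}:{ordinal}",
            kind=kind,
            bbox=BoundingBox.hull([w.bbox for w in words]),
            text=" ".join(ln.text for ln in lines),
            word_ids=[w.id for w in words],
            line_ids=[ln.id for ln in lines],
            handwritten_word_ids=[
                w.id for w in words if w.text_type is TextType.HANDWRITING
            ],
        )
        segments.append(seg)
        clean_texts[seg.id] = " ".join(builder.clean_line_texts[ln.id] for ln in lines)
        return seg

    # --- running title and page number -----------------------------------
    if spec.parity is Parity.EVEN:
        title_tokens = ["HISTORIA", "PLANTARUM"]
        page_number = 2 * (spec.seed % 400 + 1)
    else:
        title_tokens = ["De", "Herbis"]
        page_number = 2 * (spec.seed % 400 + 1) + 1
    title_width = sum(len(t) * _CHAR_W for t in title_tokens) + _SPACE_W * (len(title_tokens) - 1)
    title_line = builder.add_line(
        title_tokens, 0.5 - title_width / 2, _TITLE_TOP, TextType.PRINTED
    )
    header_ids.append(title_line.id)
    number_line = builder.add_line(
        [str(page_number)], 0.5 - _CHAR_W, _PAGE_NUMBER_TOP, TextType.PRINTED
    )
    footer_ids.append(number_line.id)

    # --- header / footer handwritten annotations --------------------------
    for band, count, base_top, collector in (
        ("header", spec.n_header_annotations, _HEADER_NOTE_TOP, header_ids),
        ("footer", spec.n_footer_annotations, _FOOTER_NOTE_TOP, footer_ids),
    ):
        kind = SegmentKind.HEADER if band == "header" else SegmentKind.FOOTER
        top = base_top
        for i in range(count):
            phrase = rng.choice(HAND_NOTE_LEXICON).split()
            ref = ["H.S.", f"{rng.randint(1, 337)}.", f"{rng.randint(1, 200)}."]
            x0 = body_x0 if spec.parity is Parity.EVEN else geo["body_x"][0]
            line = builder.add_line(phrase + ref, x0, top, TextType.HANDWRITING)
            collector.append(line.id)
            record_segment(kind, [line], i)
            top += 3 * p  # separated beyond the gap threshold
        limit = 0.06 if band == "header" else 1.0 - _WORD_HEIGHT
        if top - 3 * p + _WORD_HEIGHT > limit:
            raise GenerationError(f"{band} annotations do not fit the band")

    # --- body: plant entries and paragraphs -------------------------------
    y = _BODY_TOP
    plant_segments: list[Segment] = []
    para_count = 0
    max_entry_extent = (1 + spec.paragraph_length_range[1] + 4) * p
    for entry in range(spec.n_plant_entries):
        if y + max_entry_extent > _BODY_BOTTOM + 2 * p:
            raise GenerationError(
                f"{spec.n_plant_entries} entries at pitch {p} overrun the page"
            )
        name_tokens = rng.choice(PLANT_NAME_LEXICON).split()
        plant_line = builder.add_line(
            name_tokens, body_x0 + 0.03, y, TextType.PRINTED,
            skew=spec.skew_inflation, x_limit=body_x1,
        )
        body_line_ids.append(plant_line.id)
        plant_segments.append(record_segment(SegmentKind.PLANT_NAME, [plant_line], entry))

        n_lines = rng.randint(*spec.paragraph_length_range)
        para_lines: list[LineBlock] = []
        y += 2 * p  # entry-to-paragraph segment gap
        interrupt_at = (
            rng.randrange(1, n_lines)
            if n_lines > 1 and rng.random() < spec.handwritten_interruption_rate
            else None
        )
        for j in range(n_lines):
            if j == interrupt_at:
                # A handwritten note displaces the rest of the paragraph by
                # one line slot.
                note = rng.choice(HAND_NOTE_LEXICON).split()
                hand_line = builder.add_line(
                    note, body_x0 + 0.1, y, TextType.HANDWRITING, x_limit=body_x1
                )
                body_line_ids.append(hand_line.id)
                para_lines.append(hand_line)
                y += p
            tokens = _fill_body_line(rng, body_x0, body_x1)
            line = builder.add_line(
                tokens, body_x0, y, TextType.PRINTED,
                skew=spec.skew_inflation, x_limit=body_x1,
            )
            body_line_ids.append(line.id)
            para_lines.append(line)
            y += p
        record_segment(SegmentKind.PARAGRAPH, para_lines, para_count)
        para_count += 1
        y += p  # with the final += p above, entries sit 2 pitches apart
        if y > _BODY_BOTTOM:
            raise GenerationError(
                f"{spec.n_plant_entries} entries at pitch {p} overrun the page"
            )

    # --- margin annotations ------------------------------------------------
    pairs: list[tuple[str, str]] = []
    if spec.n_margin_annotations:
        if not plant_segments:
            raise GenerationError("margin annotations require at least one plant entry")
        plant_tops = [s.bbox.top for s in plant_segments]
        adjacent = [b - a for a, b in zip(plant_tops, plant_tops[1:])] or [2 * (_BODY_BOTTOM - _BODY_TOP)]
        span = 0.4 * min(adjacent)  # jitter bound keeps the nearest top correct
        order = list(range(len(plant_segments)))
        rng.shuffle(order)
        targets = [order[i % len(order)] for i in range(spec.n_margin_annotations)]
        per_plant: dict[int, int] = {}
        for t in targets:
            per_plant[t] = per_plant.get(t, 0) + 1
        placements: list[tuple[float, int]] = []
        for t, m in sorted(per_plant.items()):
            if (m - 1) * p >= 2 * span:
                raise GenerationError(
                    f"{m} annotations on one entry cannot fit the jitter bound"
                )
            start = plant_tops[t] + rng.uniform(-span, span - (m - 1) * p)
            placements.extend((start + j * p, t) for j in range(m))
        placements.sort()
        for i, (top, t) in enumerate(placements):
            tokens = ["H.S.", f"{rng.randint(1, 337)}.", f"{rng.randint(1, 200)}."]
            if rng.random() < 0.3:
                tokens.append(f"{rng.randint(1, 12)}.")
            line = builder.add_line(
                tokens, margin_x0, top, TextType.HANDWRITING, x_limit=margin_x1
            )
            margin_line_ids.append(line.id)
            seg = record_segment(SegmentKind.MARGIN, [line], i)
            pairs.append((seg.id, plant_segments[t].id))

    # --- bleed from the adjacent page --------------------------------------
    bleed_x0, bleed_x1 = geo["bleed_x"]
    for i in range(spec.bleed_word_count):
        top = rng.uniform(_BODY_TOP, _BODY_BOTTOM - _WORD_HEIGHT)
        token = rng.choice(BODY_LEXICON)[:4]
        line = builder.add_line(
            [token], bleed_x0, top, TextType.PRINTED, x_limit=bleed_x1 + 0.03
        )
        discarded_ids.append(line.id)

    page = builder.build()
    body_hull = BoundingBox.hull(
        [ln.bbox for ln in page.lines if ln.id in set(body_line_ids)]
    )
    layout = PageLayout(
        header_band=(0.0, 0.06),
        footer_band=(0.92, 1.0),
        margin_boundary_x=(margin_x1 + body_x0) / 2 if spec.parity is Parity.EVEN
        else (body_x1 + margin_x0) / 2,
        margin_side=geo["side"],
        body_region=body_hull,
        header_line_ids=sorted(header_ids),
        footer_line_ids=sorted(footer_ids),
        margin_line_ids=sorted(margin_line_ids),
        body_line_ids=sorted(body_line_ids),
        discarded_line_ids=sorted(discarded_ids),
    )
    gt = GroundTruth(
        page_id=page_id,
        group=spec.parity,
        layout=layout,
        segments=segments,
        pairs=pairs,
        clean_texts=clean_texts,
    )
    return page, gt


# ---------------------------------------------------------------------------
# corpus-level helpers


def ground_truth_json(gts: list[GroundTruth]) -> dict:
    """Ground truth for a corpus in the evaluation file schema."""
    return {
        "pages": [
            {
                "page_id": gt.page_id,
                "group": gt.group.value,
                "segments": [
                    {
                        "id": s.id,
                        "kind": s.kind.value,
                        "bbox": {
                            "left": s.bbox.left,
                            "top": s.bbox.top,
                            "width": s.bbox.width,
                            "height": s.bbox.height,
                        },
                        "text": s.text,
                        "clean_text": gt.clean_texts.get(s.id, s.text),
                    }
                    for s in gt.segments
                ],
                "pairs": [
                    {"margin_id": m, "plant_id": pl} for m, pl in gt.pairs
                ],
            }
            for gt in gts
        ]
    }


def generate_corpus(specs: list[SyntheticPageSpec], out_dir: str | Path) -> dict:
    """Write one block-JSON file per spec plus ground truth and a manifest.

    Returns the manifest.  Page ids must be unique across specs; the
    corpus can be regenerated byte-identically from the manifest.
    """
    if not specs:
        raise ValueError("at least one page spec required")
    out = Path(out_dir)
    (out / "pages").mkdir(parents=True, exist_ok=True)
    gts: list[GroundTruth] = []
    manifest: dict = {"pages": []}
    seen: set[str] = set()
    for spec in specs:
        page, gt = generate_page(spec)
        if page.page_id in seen:
            raise ValueError(f"duplicate page id {page.page_id}")
        seen.add(page.page_id)
        (out / "pages" / f"{page.page_id}.json").write_text(
            write_blocks(page), encoding="utf-8"
        )
        gts.append(gt)
        manifest["pages"].append(
            {
                "page_id": page.page_id,
                "seed": spec.seed,
                "parity": spec.parity.value,
                "n_plant_entries": spec.n_plant_entries,
                "n_margin_annotations": spec.n_margin_annotations,
            }
        )
    (out / "ground_truth.json").write_text(
        json.dumps(ground_truth_json(gts), indent=1, sort_keys=True), encoding="utf-8"
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest


def default_corpus_specs(
    n_pages: int, base_seed: int = 0, **overrides
) -> list[SyntheticPageSpec]:
    """Standard mixed-parity corpus: one spec per page, seeds offset from
    ``base_seed``."""
    return [
        SyntheticPageSpec(
            seed=base_seed + i,
            parity=Parity.EVEN if i % 2 == 0 else Parity.ODD,
            **overrides,
        )
        for i in range(n_pages)
    ]
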