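"""Pipeline orchestration and the structured page-record output.

Runs page-structure detection, segmentation and association on parsed
block pages and emits one JSON record per page with "header", "footer",
"plants", "margins" and "pairs" elements, plus corpus-level summaries and
crop manifests for building an image corpus of the detected segments.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, Field, model_validator

from .association import link_page
from .blocks import PageBlocks, line_pitch
from .config import PipelineConfig
from .evaluation import EvalReport, evaluate_page_set
from .page_structure import (
    LayoutError,
    PageLayout,
    Parity,
    classify_page_group,
    detect_layout,
)
from .segmentation import (
    Segment,
    SegmentKind,
    SpecimenReference,
    body_context,
    parse_specimen_reference,
    segment_headers_footers,
    segment_margins,
    segment_paragraphs,
    split_plant_names,
)

logger = logging.getLogger(__name__)


class BBoxModel(BaseModel):
    left: float
    top: float
    width: float
    height: float


class TextElement(BaseModel):
    id: str
    text: str
    bbox: BBoxModel


class ReferenceModel(BaseModel):
    volume: int
    folio: int
    specimen: int | None = None


class MarginElement(TextElement):
    parsed_references: list[ReferenceModel] = Field(default_factory=list)
    residue: str = ""


class PairModel(BaseModel):
    margin_id: str
    plant_id: str
    distance: float
    ambiguous: bool = False


class PageRecord(BaseModel):
    """Structured output for one page; referentially self-contained."""

    page_id: str
    group: str  # ODD | EVEN | UNKNOWN
    header: list[TextElement] = Field(default_factory=list)
    footer: list[TextElement] = Field(default_factory=list)
    plants: list[TextElement] = Field(default_factory=list)
    margins: list[MarginElement] = Field(default_factory=list)
    paragraphs: list[TextElement] = Field(default_factory=list)
    pairs: list[PairModel] = Field(default_factory=list)
    unlinked: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_referential_integrity(self) -> "PageRecord":
        plant_ids = {p.id for p in self.plants}
        margin_ids = {m.id for m in self.margins}
        all_ids = [e.id for e in self.header + self.footer + self.plants + self.margins]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError(f"duplicate element ids on page {self.page_id}")
        for pair in self.pairs:
            if pair.plant_id not in plant_ids:
                raise ValueError(f"pair references unknown plant {pair.plant_id}")
            if pair.margin_id not in margin_ids:
                raise ValueError(f"pair references unknown margin {pair.margin_id}")
        for mid in self.unlinked:
            if mid not in margin_ids:
                raise ValueError(f"unlinked references unknown margin {mid}")
        return self


class CorpusSummary(BaseModel):
    """Aggregate counts over page records (one row of the output table)."""

    pages: int = 0
    headers_segments: int = 0
    footers_segments: int = 0
    margins_segments: int = 0
    printed_plant_names: int = 0
    handwritten_plant_names: int = 0
    specimen_references: int = 0
    failed_pages: int = 0

    def __add__(self, other: "CorpusSummary") -> "CorpusSummary":
        return CorpusSummary(
            **{k: getattr(self, k) + getattr(other, k) for k in type(self).model_fields}
        )


def summarise(records: Sequence[PageRecord], failed: int = 0) -> CorpusSummary:
    """Exact column sums over per-page records."""
    return CorpusSummary(
        pages=len(records),
        headers_segments=sum(len(r.header) for r in records),
        footers_segments=sum(len(r.footer) for r in records),
        margins_segments=sum(len(r.margins) for r in records),
        printed_plant_names=sum(len(r.plants) for r in records),
        handwritten_plant_names=sum(len(r.header) + len(r.footer) for r in records),
        specimen_references=sum(
            len(m.parsed_references) for r in records for m in r.margins
        ),
        failed_pages=failed,
    )


def _element(seg: Segment) -> TextElement:
    return TextElement(
        id=seg.id,
        text=seg.text,
        bbox=BBoxModel(
            left=seg.bbox.left, top=seg.bbox.top, width=seg.bbox.width, height=seg.bbox.height
        ),
    )


def _margin_element(seg: Segment) -> MarginElement:
    refs, residue = parse_specimen_reference(seg.text)
    return MarginElement(
        **_element(seg).model_dump(),
        parsed_references=[
            ReferenceModel(volume=r.volume, folio=r.folio, specimen=r.specimen) for r in refs
        ],
        residue=residue,
    )


def mobilise_segments(
    page: PageBlocks, cfg: PipelineConfig | None = None
) -> tuple[list[Segment], PageLayout, Parity]:
    """Run layout detection and segmentation; returns all typed segments."""
    cfg = cfg or PipelineConfig()
    if not page.lines:  # a blank page is empty output, not a failure
        empty_layout = PageLayout(
            header_band=(0.0, cfg.header_frac),
            footer_band=(cfg.footer_frac, 1.0),
            margin_boundary_x=0.0,
            margin_side=cfg.even_margin_side.upper(),
            body_region=page.page_bbox,
        )
        return [], empty_layout, Parity.UNKNOWN
    group = classify_page_group(page, cfg)
    layout = detect_layout(page, group, cfg)
    pitch = line_pitch(page, default=cfg.default_pitch)
    by_id = {ln.id: ln for ln in page.lines}
    prefix = f"{page.page_id}:"

    body_lines = [by_id[i] for i in layout.body_line_ids]
    paragraphs = segment_paragraphs(page, body_lines, pitch, cfg, id_prefix=prefix)
    ctx = body_context(page, body_lines, pitch)
    plants, prose = split_plant_names(page, paragraphs, ctx, cfg, id_prefix=prefix)
    margins = segment_margins(
        page, [by_id[i] for i in layout.margin_line_ids], pitch, cfg, id_prefix=prefix
    )
    bands = segment_headers_footers(
        page,
        [by_id[i] for i in layout.header_line_ids],
        [by_id[i] for i in layout.footer_line_ids],
        pitch,
        cfg,
        id_prefix=prefix,
    )
    return bands + plants + prose + margins, layout, group.value


def mobilise_page(page: PageBlocks, cfg: PipelineConfig | None = None) -> PageRecord:
    """Produce the structured record for one page; deterministic given cfg."""
    cfg = cfg or PipelineConfig()
    segments, _, parity = mobilise_segments(page, cfg)
    of = lambda kind: [s for s in segments if s.kind is kind]
    margins = of(SegmentKind.MARGIN)
    plants = of(SegmentKind.PLANT_NAME)
    pairs, unlinked = link_page(margins, plants, cfg.ambiguity_eps)
    return PageRecord(
        page_id=page.page_id,
        group=parity,
        header=[_element(s) for s in of(SegmentKind.HEADER)],
        footer=[_element(s) for s in of(SegmentKind.FOOTER)],
        plants=[_element(s) for s in plants],
        margins=[_margin_element(s) for s in margins],
        paragraphs=[_element(s) for s in of(SegmentKind.PARAGRAPH)],
        pairs=[
            PairModel(
                margin_id=pr.margin_segment_id,
                plant_id=pr.plant_segment_id,
                distance=pr.distance,
                ambiguous=pr.ambiguous,
            )
            for pr in pairs
        ],
        unlinked=unlinked,
    )


def mobilise_corpus(
    pages: Sequence[PageBlocks], cfg: PipelineConfig | None = None
) -> tuple[list[PageRecord], CorpusSummary]:
    """Process a corpus page by page; per-page failures are logged and
    counted, not fatal."""
    if not pages:
        raise ValueError("empty corpus")
    records: list[PageRecord] = []
    failed = 0
    for page in pages:
        try:
            records.append(mobilise_page(page, cfg))
        except (LayoutError, ValueError) as exc:
            logger.error("page %s failed: %s", page.page_id, exc)
            failed += 1
    return records, summarise(records, failed)


# ---------------------------------------------------------------------------
# crop manifests and image crops


def crop_manifest(record: PageRecord, page: PageBlocks) -> list[dict]:
    """Pixel boxes for every segment of a record, clipped to the page.

    Fractional coordinates are floored on the left/top edge and ceiled on
    the right/bottom so the crop never cuts into glyphs.
    """
    out = []
    for element in record.header + record.footer + record.plants + record.margins:
        b = element.bbox
        x0 = max(0, math.floor(b.left * page.width_px))
        y0 = max(0, math.floor(b.top * page.height_px))
        x1 = min(page.width_px, math.ceil((b.left + b.width) * page.width_px))
        y1 = min(page.height_px, math.ceil((b.top + b.height) * page.height_px))
        out.append({"segment_id": element.id, "pixel_box": (x0, y0, x1, y1)})
    return out


def crop_images(
    manifest: list[dict], image_path: str | Path | None, out_dir: str | Path,
    page: PageBlocks | None = None,
) -> list[Path]:
    """Cut one image per manifest entry plus an outlined overview.

    Optional: with no image supplied this is a logged no-op.  The raster
    must match the page's pixel dimensions.
    """
    if image_path is None:
        logger.info("no page image supplied; skipping crops")
        return []
    from PIL import Image, ImageDraw

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = Image.open(image_path)
    if page is not None and img.size != (page.width_px, page.height_px):
        raise ValueError(
            f"image is {img.size[0]}x{img.size[1]} px, "
            f"expected {page.width_px}x{page.height_px}"
        )
    written: list[Path] = []
    overview = img.convert("RGB")
    draw = ImageDraw.Draw(overview)
    for entry in manifest:
        x0, y0, x1, y1 = entry["pixel_box"]
        crop = img.crop((x0, y0, x1, y1))
        path = out / f"{entry['segment_id'].replace(':', '_')}.png"
        crop.save(path)
        written.append(path)
        draw.rectangle((x0, y0, x1 - 1, y1 - 1), outline=(200, 30, 30), width=4)
    overview_path = out / "overview.png"
    overview.save(overview_path)
    written.append(overview_path)
    return written


# ---------------------------------------------------------------------------
# evaluation plumbing: records and GT files -> EvalReport


def _segments_from_eval_page(page: dict) -> tuple[list[Segment], list[tuple[str, str]]]:
    from .blocks import BoundingBox

    segs = [
        Segment(
            id=s["id"],
            kind=SegmentKind(s["kind"]),
            bbox=BoundingBox(
                s["bbox"]["left"], s["bbox"]["top"], s["bbox"]["width"], s["bbox"]["height"]
            ),
            text=s.get("text", ""),
            word_ids=list(s.get("word_ids", [])),
            line_ids=list(s.get("line_ids", [])),
        )
        for s in page["segments"]
    ]
    pairs = [(p["margin_id"], p["plant_id"]) for p in page.get("pairs", [])]
    return segs, pairs


def record_to_eval_page(record: PageRecord) -> dict:
    """Project a page record onto the evaluation file schema."""
    segments = []
    for kind, elements in (
        ("HEADER", record.header),
        ("FOOTER", record.footer),
        ("PLANT_NAME", record.plants),
        ("MARGIN", record.margins),
        ("PARAGRAPH", record.paragraphs),
    ):
        for e in elements:
            segments.append(
                {
                    "id": e.id,
                    "kind": kind,
                    "bbox": e.bbox.model_dump(),
                    "text": e.text,
                }
            )
    return {
        "page_id": record.page_id,
        "segments": segments,
        "pairs": [{"margin_id": p.margin_id, "plant_id": p.plant_id} for p in record.pairs],
    }


def evaluate_records(
    pred_pages: list[dict],
    gt_pages: list[dict],
    threshold: float = 0.7,
    with_cer: bool = True,
) -> EvalReport:
    """Evaluate prediction pages against ground-truth pages (file schema)."""
    pred = {p["page_id"]: _segments_from_eval_page(p) for p in pred_pages}
    gt = {p["page_id"]: _segments_from_eval_page(p) for p in gt_pages}
    clean = None
    if with_cer:
        clean = {
            s["id"]: s.get("clean_text", s.get("text", ""))
            for p in gt_pages
            for s in p["segments"]
        }
    return evaluate_page_set(pred, gt, threshold=threshold, clean_texts=clean)
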