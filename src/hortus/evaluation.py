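"""Evaluation protocol: CER, IoU segment matching, precision/recall/F1.

Transcription quality is measured by the character error rate: the
Levenshtein distance between hypothesis and ground truth, divided by the
ground-truth character count and scaled to per cent.  Layout quality is
measured by matching predicted to ground-truth segments when their
bounding-box intersection-over-union exceeds a threshold (0.7), then
scoring precision, recall and F1 per category; relationship links are
scored the same way over matched endpoints.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .blocks import BoundingBox
from .segmentation import Segment


@dataclass(frozen=True)
class TranscriptionPair:
    ground_truth: str
    hypothesis: str


def levenshtein(a: str, b: str) -> int:
    """Uniform-cost edit distance (insert = delete = substitute = 1)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def cer(pair: TranscriptionPair) -> float:
    """Character error rate, in per cent of the ground-truth length.

    ``100 x Levenshtein(gt, hyp) / |gt|`` after NFC normalisation; can
    exceed 100 when the hypothesis carries many insertions.
    """
    gt = unicodedata.normalize("NFC", pair.ground_truth)
    hyp = unicodedata.normalize("NFC", pair.hypothesis)
    if not gt:
        raise ValueError("CER is undefined for empty ground truth")
    return 100.0 * levenshtein(gt, hyp) / len(gt)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 for a zero-area union."""
    ix = max(0.0, min(a.right, b.right) - max(a.left, b.left))
    iy = max(0.0, min(a.bottom, b.bottom) - max(a.top, b.top))
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    return min(1.0, inter / union)


@dataclass
class Matching:
    """One-to-one segment matching at an IoU threshold."""

    matched: list[tuple[str, str, float]] = field(default_factory=list)  # (pred, gt, iou)
    false_positive_ids: list[str] = field(default_factory=list)
    false_negative_ids: list[str] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.matched)

    @property
    def mean_iou(self) -> float:
        if not self.matched:
            return 0.0
        return sum(m[2] for m in self.matched) / len(self.matched)

    def pred_to_gt(self) -> dict[str, str]:
        return {p: g for p, g, _ in self.matched}


def match_segments(
    pred: Sequence[Segment], gt: Sequence[Segment], threshold: float = 0.7
) -> Matching:
    """Greedily match predicted to ground-truth segments by descending IoU.

    Only pairs with IoU strictly above ``threshold`` are candidates; each
    segment joins at most one match.  Greedy selection on descending IoU is
    transparent and, for the well-separated overlaps typical of page
    segments, agrees with the optimal assignment.
    """
    candidates = [
        (iou(p.bbox, g.bbox), pi, gi)
        for pi, p in enumerate(pred)
        for gi, g in enumerate(gt)
    ]
    candidates = [c for c in candidates if c[0] > threshold]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_pred: set[int] = set()
    used_gt: set[int] = set()
    out = Matching()
    for score, pi, gi in candidates:
        if pi in used_pred or gi in used_gt:
            continue
        used_pred.add(pi)
        used_gt.add(gi)
        out.matched.append((pred[pi].id, gt[gi].id, score))
    out.false_positive_ids = [p.id for i, p in enumerate(pred) if i not in used_pred]
    out.false_negative_ids = [g.id for i, g in enumerate(gt) if i not in used_gt]
    return out


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 = 2PR/(P+R); 0 where a denominator is 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def f1_from_pr(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate_relationships(
    pred_pairs: Iterable[tuple[str, str]],
    gt_pairs: Iterable[tuple[str, str]],
    margin_matching: Matching,
    plant_matching: Matching,
) -> tuple[float, float, float]:
    """Score predicted (margin, plant) links against the ground truth.

    A predicted pair is a true positive iff both endpoints matched
    ground-truth segments and the ground truth links those same two.
    """
    m_map = margin_matching.pred_to_gt()
    p_map = plant_matching.pred_to_gt()
    gt_set = set(gt_pairs)
    pred_list = list(pred_pairs)
    tp = sum(
        1
        for margin_id, plant_id in pred_list
        if (m_map.get(margin_id), p_map.get(plant_id)) in gt_set
    )
    fp = len(pred_list) - tp
    fn = len(gt_set) - tp
    return precision_recall_f1(tp, fp, fn)


@dataclass
class CategoryScore:
    total_gt: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    mean_iou: float


@dataclass
class EvalReport:
    """Per-category segmentation scores plus relationship and CER figures."""

    categories: dict[str, CategoryScore] = field(default_factory=dict)
    relationships: tuple[float, float, float] = (0.0, 0.0, 0.0)
    relationship_total_gt: int = 0
    mean_iou: float = 0.0
    cer_by_type: dict[str, float] = field(default_factory=dict)

    def rounded(self) -> dict:
        """Report dict: P/R/F1 to 2 decimals, CER percentages to 1."""
        return {
            "categories": {
                k: {
                    "total_gt": v.total_gt,
                    "recall": round(v.recall, 2),
                    "precision": round(v.precision, 2),
                    "f1": round(v.f1, 2),
                }
                for k, v in self.categories.items()
            },
            "relationships": {
                "total_gt": self.relationship_total_gt,
                "precision": round(self.relationships[0], 2),
                "recall": round(self.relationships[1], 2),
                "f1": round(self.relationships[2], 2),
            },
            "mean_iou": round(self.mean_iou, 2),
            "cer_by_type": {k: round(v, 1) for k, v in self.cer_by_type.items()},
        }


def evaluate_page_set(
    pred_by_page: Mapping[str, tuple[Sequence[Segment], Sequence[tuple[str, str]]]],
    gt_by_page: Mapping[str, tuple[Sequence[Segment], Sequence[tuple[str, str]]]],
    threshold: float = 0.7,
    clean_texts: Mapping[str, str] | None = None,
) -> EvalReport:
    """Evaluate predicted segments and links over a set of pages.

    ``pred_by_page``/``gt_by_page`` map a page id to (segments, pairs)
    where pairs are (margin_segment_id, plant_segment_id).  Segments are
    matched per page and per category; relationship scores are pooled over
    pages.  When ``clean_texts`` maps ground-truth segment ids to reference
    transcriptions, a CER per category is reported over matched segments.
    """
    kinds = ["HEADER", "FOOTER", "MARGIN", "PLANT_NAME", "PARAGRAPH"]
    counts = {k: [0, 0, 0] for k in kinds}  # tp, fp, fn
    gt_totals = {k: 0 for k in kinds}
    iou_sum, iou_n = 0.0, 0
    rel_tp = rel_fp = rel_fn = 0
    rel_gt_total = 0
    cer_sums: dict[str, list[float]] = {k: [] for k in kinds}

    for page_id in sorted(set(pred_by_page) | set(gt_by_page)):
        pred_segs, pred_pairs = pred_by_page.get(page_id, ([], []))
        gt_segs, gt_pairs = gt_by_page.get(page_id, ([], []))
        matchings: dict[str, Matching] = {}
        for kind in kinds:
            p = [s for s in pred_segs if s.kind.value == kind]
            g = [s for s in gt_segs if s.kind.value == kind]
            gt_totals[kind] += len(g)
            m = match_segments(p, g, threshold)
            matchings[kind] = m
            counts[kind][0] += m.tp
            counts[kind][1] += len(m.false_positive_ids)
            counts[kind][2] += len(m.false_negative_ids)
            iou_sum += sum(x[2] for x in m.matched)
            iou_n += m.tp
            if clean_texts is not None:
                pred_text = {s.id: s.text for s in p}
                for pred_id, gt_id, _ in m.matched:
                    ref = clean_texts.get(gt_id)
                    if ref:
                        cer_sums[kind].append(
                            cer(TranscriptionPair(ref, pred_text[pred_id]))
                        )
        m_map = matchings["MARGIN"].pred_to_gt()
        p_map = matchings["PLANT_NAME"].pred_to_gt()
        gt_pair_set = {(a, b) for a, b in gt_pairs}
        rel_gt_total += len(gt_pair_set)
        tp_here = sum(
            1 for a, b in pred_pairs if (m_map.get(a), p_map.get(b)) in gt_pair_set
        )
        rel_tp += tp_here
        rel_fp += len(list(pred_pairs)) - tp_here
        rel_fn += len(gt_pair_set) - tp_here

    report = EvalReport()
    for kind in kinds:
        tp, fp, fn = counts[kind]
        if gt_totals[kind] == 0 and tp + fp == 0:
            continue
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        report.categories[kind] = CategoryScore(
            total_gt=gt_totals[kind], tp=tp, fp=fp, fn=fn,
            precision=p, recall=r, f1=f1,
            mean_iou=0.0,
        )
    report.relationships = precision_recall_f1(rel_tp, rel_fp, rel_fn)
    report.relationship_total_gt = rel_gt_total
    report.mean_iou = iou_sum / iou_n if iou_n else 0.0
    report.cer_by_type = {
        k: sum(v) / len(v) for k, v in cer_sums.items() if v
    }
    return report
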