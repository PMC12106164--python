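"""CER, IoU matching and precision/recall/F1 arithmetic."""

import random
import string
import unicodedata

import pytest

import hortus as h
from hortus.blocks import BoundingBox
from hortus.evaluation import TranscriptionPair, f1_from_pr, match_segments
from hortus.segmentation import SegmentKind

from conftest import make_segment


def wagner_fischer(a: str, b: str) -> int:
    """Independent dynamic-programming edit distance (uniform costs)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


class TestCER:
    @pytest.mark.parametrize(
        "gt, hyp, expected",
        [
            ("abc", "abc", 0.0),
            ("abc", "", 100.0),
            # two substitutions over 14 ground-truth characters
            ("150.26. 105.37", "156.26, 105.37", pytest.approx(100 * 2 / 14)),
        ],
    )
    def test_examples(self, gt, hyp, expected):
        assert h.cer(TranscriptionPair(gt, hyp)) == expected

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            h.cer(TranscriptionPair("", "abc"))

    def test_can_exceed_100_with_insertions(self):
        assert h.cer(TranscriptionPair("ab", "abcdefgh")) > 100

    def test_identity_is_zero(self, rng):
        for _ in range(20):
            s = "".join(rng.choices(string.printable, k=rng.randint(1, 40)))
            assert h.cer(TranscriptionPair(s, s)) == 0.0

    def test_nfc_equivalent_encodings_identical(self):
        nfd = unicodedata.normalize("NFD", "Hortulí siccí")
        nfc = unicodedata.normalize("NFC", "Hortulí siccí")
        assert nfd != nfc
        assert h.cer(TranscriptionPair(nfc, nfd)) == 0.0

    def test_matches_wagner_fischer_dp_on_random_pairs(self):
        rng = random.Random(99)
        alphabet = string.ascii_letters + string.digits + " .,"
        for _ in range(1000):
            a = "".join(rng.choices(alphabet, k=rng.randint(1, 30)))
            b = "".join(rng.choices(alphabet, k=rng.randint(0, 30)))
            expected = 100 * wagner_fischer(a, b) / len(a)
            assert h.cer(TranscriptionPair(a, b)) == pytest.approx(expected)


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(0.1, 0.1, 0.3, 0.2)
        assert h.iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert h.iou(BoundingBox(0, 0, 0.1, 0.1), BoundingBox(0.5, 0.5, 0.1, 0.1)) == 0.0

    def test_analytic_half_overlap(self):
        assert h.iou(BoundingBox(0, 0, 1, 1), BoundingBox(0.5, 0, 0.5, 1)) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(100):
            a = BoundingBox(rng.uniform(0, 0.5), rng.uniform(0, 0.5),
                            rng.uniform(0.01, 0.5), rng.uniform(0.01, 0.5))
            b = BoundingBox(rng.uniform(0, 0.5), rng.uniform(0, 0.5),
                            rng.uniform(0.01, 0.5), rng.uniform(0.01, 0.5))
            assert h.iou(a, b) == pytest.approx(h.iou(b, a))
            assert 0 <= h.iou(a, b) <= 1

    def test_zero_area_union(self):
        z = BoundingBox(0.2, 0.2, 0, 0)
        assert h.iou(z, z) == 0.0


def _seg(i, left, top, w=0.1, hgt=0.05, kind=SegmentKind.MARGIN):
    return make_segment(f"s{i}", kind, top, left=left, width=w, height=hgt)


class TestMatchSegments:
    def test_perfect_prediction(self):
        gt = [_seg(i, 0.1, 0.1 + 0.2 * i) for i in range(3)]
        m = match_segments(gt, gt)
        assert m.tp == 3 and m.mean_iou == pytest.approx(1.0)
        assert m.false_positive_ids == [] and m.false_negative_ids == []

    def test_strict_threshold_excludes_iou_below(self):
        # identical height boxes shifted so IoU = (0.05-d)/(0.05+d); d chosen
        # for IoU just under 0.7
        d = 0.05 * 0.3 / 1.7 + 1e-4
        gt = [_seg(0, 0.1, 0.5)]
        pred = [_seg(1, 0.1, 0.5 + d)]
        assert h.iou(pred[0].bbox, gt[0].bbox) < 0.7
        m = match_segments(pred, gt)
        assert m.tp == 0 and m.false_positive_ids == ["s1"] and m.false_negative_ids == ["s0"]

    def test_exactly_at_threshold_excluded(self):
        gt = [_seg(0, 0.0, 0.0, w=1.0, hgt=0.7)]
        pred = [_seg(1, 0.0, 0.0, w=1.0, hgt=1.0)]
        assert h.iou(pred[0].bbox, gt[0].bbox) == pytest.approx(0.7)
        assert match_segments(pred, gt, threshold=0.7).tp == 0

    def test_one_to_one(self):
        gt = [_seg(0, 0.1, 0.5)]
        pred = [_seg(1, 0.1, 0.5), _seg(2, 0.1, 0.505)]
        m = match_segments(pred, gt)
        assert m.tp == 1
        matched_preds = [p for p, _, _ in m.matched]
        assert len(matched_preds) == len(set(matched_preds)) == 1

    def test_greedy_equals_hungarian_on_separated_instances(self):
        from scipy.optimize import linear_sum_assignment
        import numpy as np

        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(1, 6)
            gt = [_seg(f"g{i}", 0.1, 0.04 + 0.15 * i) for i in range(n)]
            pred = [
                _seg(f"p{i}", 0.1, 0.04 + 0.15 * i + rng.uniform(-0.004, 0.004))
                for i in range(n)
            ]
            m = match_segments(pred, gt)
            cost = np.array([[-h.iou(p.bbox, g.bbox) for g in gt] for p in pred])
            rows, cols = linear_sum_assignment(cost)
            optimal = {(pred[r].id, gt[c].id) for r, c in zip(rows, cols)
                       if -cost[r, c] > 0.7}
            assert {(p, g) for p, g, _ in m.matched} == optimal


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "p, r, expected",
        [(0.97, 0.97, 0.97), (1.0, 0.95, 0.97), (0.92, 0.87, 0.89),
         (0.9, 0.93, 0.91), (0.88, 0.84, 0.86)],
    )
    def test_harmonic_mean_reproduces_published_rows(self, p, r, expected):
        assert round(f1_from_pr(p, r), 2) == expected

    def test_counts_to_scores(self):
        p, r, f1 = h.precision_recall_f1(8, 2, 2)
        assert (p, r) == (0.8, 0.8) and f1 == pytest.approx(0.8)

    def test_degenerate_zero_counts(self):
        assert h.precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_f1_between_min_and_max(self, rng):
        for _ in range(100):
            tp, fp, fn = rng.randint(1, 50), rng.randint(0, 50), rng.randint(0, 50)
            p, r, f1 = h.precision_recall_f1(tp, fp, fn)
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            h.precision_recall_f1(-1, 0, 0)


class TestRelationships:
    def _matchings(self, margins, plants):
        return match_segments(margins, margins), match_segments(plants, plants)

    def test_identical_pairs_perfect_score(self):
        margins = [_seg(f"m{i}", 0.05, 0.1 + 0.2 * i) for i in range(3)]
        plants = [_seg(f"q{i}", 0.3, 0.1 + 0.2 * i, kind=SegmentKind.PLANT_NAME)
                  for i in range(3)]
        pairs = [(m.id, p.id) for m, p in zip(margins, plants)]
        mm, pm = self._matchings(margins, plants)
        assert h.evaluate_relationships(pairs, pairs, mm, pm) == (1.0, 1.0, 1.0)

    def test_one_swapped_link_among_n(self):
        n = 5
        margins = [_seg(f"m{i}", 0.05, 0.1 + 0.15 * i) for i in range(n)]
        plants = [_seg(f"q{i}", 0.3, 0.1 + 0.15 * i, kind=SegmentKind.PLANT_NAME)
                  for i in range(n)]
        gt_pairs = [(m.id, p.id) for m, p in zip(margins, plants)]
        pred = list(gt_pairs)
        pred[0] = (margins[0].id, plants[1].id)  # one wrong endpoint
        mm, pm = self._matchings(margins, plants)
        p, r, f1 = h.evaluate_relationships(pred, gt_pairs, mm, pm)
        assert r == pytest.approx((n - 1) / n)
        assert p == pytest.approx((n - 1) / n)

    def test_unmatched_endpoint_cannot_be_true_positive(self):
        margins = [_seg("m0", 0.05, 0.1)]
        plants = [_seg("q0", 0.3, 0.1, kind=SegmentKind.PLANT_NAME)]
        mm = match_segments([], margins)  # margin missed by the segmenter
        pm = match_segments(plants, plants)
        p, r, f1 = h.evaluate_relationships([("m0", "q0")], [("m0", "q0")], mm, pm)
        assert (p, r, f1) == (0.0, 0.0, 0.0)
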