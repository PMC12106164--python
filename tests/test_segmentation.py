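"""Paragraph segmentation, plant-name classification, margin/band
segmentation and specimen-reference parsing."""

import pytest

import hortus as h
from hortus.blocks import BoundingBox, LineBlock, PageBlocks, TextType, WordBlock
from hortus.segmentation import (
    SegmentKind,
    SpecimenReference,
    body_context,
    split_plant_names,
)


def _page_of_lines(rows, body_left=0.1):
    """rows: list of (top, text, text_type, indent) body lines."""
    words, lines = {}, []
    for i, (top, text, ttype, indent) in enumerate(rows):
        ids = []
        x = body_left + indent
        for j, token in enumerate(text.split()):
            wid = f"w{i}-{j}"
            width = 0.012 * len(token)
            words[wid] = WordBlock(id=wid, text=token, text_type=ttype,
                                   bbox=BoundingBox(x, top, width, 0.011))
            ids.append(wid)
            x += width + 0.005
        lines.append(LineBlock(id=f"l{i}", text=text, bbox=BoundingBox(body_left + indent, top, x, 0.012),
                               child_word_ids=tuple(ids)))
    return PageBlocks(page_id="t", lines=lines, words=words)


P = TextType.PRINTED
HW = TextType.HANDWRITING
PITCH = 0.015


class TestParagraphs:
    def test_three_paragraphs_with_double_pitch_gaps(self, clean_page):
        page, gt = clean_page
        body = [ln for ln in page.lines if ln.id in set(gt.layout.body_line_ids)]
        segs = h.segment_paragraphs(page, body, PITCH)
        gt_partition = sorted(
            tuple(sorted(s.word_ids))
            for s in gt.segments
            if s.kind in (SegmentKind.PARAGRAPH, SegmentKind.PLANT_NAME)
        )
        assert sorted(tuple(sorted(s.word_ids)) for s in segs) == gt_partition

    def test_handwritten_interruption_does_not_split(self):
        rows = [
            (0.10, "caulibus tenuibus serratis", P, 0),
            (0.115, "foliis hirsutis minor", P, 0),
            (0.130, "Chamaedrys spuria", HW, 0.02),  # interrupts the paragraph
            (0.145, "semine parvo rotundo", P, 0),
            (0.160, "radice fibrosa alba", P, 0),
        ]
        page = _page_of_lines(rows)
        segs = h.segment_paragraphs(page, page.lines, PITCH)
        assert len(segs) == 1
        assert set(segs[0].line_ids) == {f"l{i}" for i in range(5)}
        assert segs[0].handwritten_word_ids  # flagged, not dropped

    def test_single_line_is_one_paragraph(self):
        page = _page_of_lines([(0.2, "foliis caule", P, 0)])
        segs = h.segment_paragraphs(page, page.lines, PITCH)
        assert len(segs) == 1 and segs[0].kind is SegmentKind.PARAGRAPH

    def test_empty_body_gives_empty_list(self, clean_page):
        assert h.segment_paragraphs(clean_page[0], [], PITCH) == []

    def test_word_conservation(self, clean_page):
        page, gt = clean_page
        body = [ln for ln in page.lines if ln.id in set(gt.layout.body_line_ids)]
        segs = h.segment_paragraphs(page, body, PITCH)
        seg_words = [w for s in segs for w in s.word_ids]
        assert sorted(seg_words) == sorted(w for ln in body for w in ln.child_word_ids)
        assert len(seg_words) == len(set(seg_words))

    @pytest.mark.parametrize("mult_low, mult_high", [(1.0, 1.6), (1.6, 3.0)])
    def test_paragraph_count_monotone_in_gap_multiplier(self, clean_page, mult_low, mult_high):
        page, gt = clean_page
        body = [ln for ln in page.lines if ln.id in set(gt.layout.body_line_ids)]
        n = lambda m: len(h.segment_paragraphs(
            page, body, PITCH, h.PipelineConfig(para_gap_mult=m)))
        assert n(mult_low) >= n(mult_high)

    def test_segments_vertically_ordered(self, clean_page):
        page, gt = clean_page
        body = [ln for ln in page.lines if ln.id in set(gt.layout.body_line_ids)]
        tops = [s.bbox.top for s in h.segment_paragraphs(page, body, PITCH)]
        assert tops == sorted(tops)


class TestPlantName:
    def _classify(self, rows, body_left_rows=None):
        page = _page_of_lines(rows + (body_left_rows or []))
        target = _page_of_lines(rows)
        segs = h.segment_paragraphs(target, target.lines, PITCH)
        assert len(segs) == 1
        ctx = body_context(page, page.lines, PITCH)
        return h.classify_plant_name(target, segs[0], ctx)

    # flush-left filler fixing the body-left envelope at 0.1
    FLUSH = [(0.5, "foliis caule radice", P, 0), (0.515, "semine odore locis", P, 0),
             (0.53, "annua perennis floret", P, 0)]

    def test_indented_capitalised_single_line_is_plant_name(self):
        assert self._classify([(0.1, "Corymbiferis flore albo", P, 0.03)], self.FLUSH)

    def test_all_uppercase_non_indented_is_plant_name(self):
        assert self._classify([(0.1, "GRAMEN PRATENSE MINUS", P, 0)], self.FLUSH)

    def test_abbreviation_start_is_plant_name(self):
        assert self._classify([(0.1, "J.B. medica magna turbinata", P, 0)], self.FLUSH)

    def test_long_lowercase_paragraph_is_not(self):
        rows = [(0.1 + i * PITCH, "foliis caule radice semine", P, 0) for i in range(6)]
        assert not self._classify(rows, self.FLUSH)

    def test_requires_paragraph_kind(self, clean_page):
        page, gt = clean_page
        margin = gt.segments_of(SegmentKind.MARGIN)[0]
        with pytest.raises(ValueError):
            h.classify_plant_name(page, margin, body_context(page, page.lines, PITCH))

    def test_split_recovers_generator_labels(self, clean_page, odd_page):
        for page, gt in (clean_page, odd_page):
            body_ids = set(gt.layout.body_line_ids)
            body = [ln for ln in page.lines if ln.id in body_ids]
            paragraphs = h.segment_paragraphs(page, body, PITCH)
            plants, prose = split_plant_names(
                page, paragraphs, body_context(page, body, PITCH))
            gt_plants = sorted(
                tuple(sorted(s.word_ids)) for s in gt.segments_of(SegmentKind.PLANT_NAME))
            assert sorted(tuple(sorted(s.word_ids)) for s in plants) == gt_plants


class TestMargins:
    def test_hs_initials_split_table_style_lines(self):
        # annotation texts mirroring the handwritten specimen references
        rows = [
            (0.10, "H.S. 114. p.29.1.", HW, 0),
            (0.115, "229.5. 205.229", HW, 0),   # continuation folios
            (0.130, "H.S. 150.26.", HW, 0),
        ]
        page = _page_of_lines(rows, body_left=0.04)
        segs = h.segment_margins(page, page.lines, PITCH)
        assert [s.line_ids for s in segs] == [["l0", "l1"], ["l2"]]

    @pytest.mark.parametrize("prefix", ["H.S.", "H. S.", "HS", "h.s."])
    def test_fuzzy_initial_variants_start_segments(self, prefix):
        rows = [(0.1, f"{prefix} 3 101", HW, 0), (0.115, f"{prefix} 4 17", HW, 0)]
        page = _page_of_lines(rows, body_left=0.04)
        assert len(h.segment_margins(page, page.lines, PITCH)) == 2

    def test_wide_gap_starts_segment_without_initials(self):
        rows = [(0.1, "H.S. 3 101", HW, 0), (0.2, "17. 4.", HW, 0)]
        page = _page_of_lines(rows, body_left=0.04)
        assert len(h.segment_margins(page, page.lines, PITCH)) == 2

    def test_empty_margin(self, clean_page):
        assert h.segment_margins(clean_page[0], [], PITCH) == []

    def test_single_line_segment(self):
        page = _page_of_lines([(0.1, "H.S. 3 101", HW, 0)], body_left=0.04)
        segs = h.segment_margins(page, page.lines, PITCH)
        assert len(segs) == 1 and segs[0].kind is SegmentKind.MARGIN


class TestHeaderFooterBands:
    def test_footer_with_one_handwritten_line(self):
        page = _page_of_lines([(0.95, "Medica cochleata H.S. 14. 3.", HW, 0)])
        segs = h.segment_headers_footers(page, [], page.lines, PITCH)
        assert [s.kind for s in segs] == [SegmentKind.FOOTER]

    def test_two_header_annotations_split_on_triple_pitch_gap(self):
        page, gt = h.generate_page(h.SyntheticPageSpec(seed=31, n_header_annotations=2))
        header_ids = set(gt.layout.header_line_ids)
        header = [ln for ln in page.lines if ln.id in header_ids]
        segs = h.segment_headers_footers(page, header, [], PITCH)
        assert len(segs) == 2
        assert all(s.kind is SegmentKind.HEADER for s in segs)

    def test_printed_running_title_yields_no_segment(self):
        page = _page_of_lines([(0.02, "HISTORIA PLANTARUM", P, 0)])
        assert h.segment_headers_footers(page, page.lines, [], PITCH) == []


class TestSpecimenReferences:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("H.S. 3 101", [SpecimenReference(3, 101)]),
            ("", []),
            ("H.S. 114. p.29. 1.", [SpecimenReference(114, 29, 1)]),
            ("H. S. 150.26.", [SpecimenReference(150, 26)]),
            ("H.S. 3 101 H.S. 4 17", [SpecimenReference(3, 101), SpecimenReference(4, 17)]),
        ],
    )
    def test_reference_extraction(self, text, expected):
        refs, _ = h.parse_specimen_reference(text)
        assert refs == expected

    def test_unparseable_text_goes_to_residue(self):
        refs, residue = h.parse_specimen_reference("Morison sursum tendentibus")
        assert refs == [] and "Morison" in residue

    def test_never_raises_on_degraded_transcription(self):
        for text in ["H.S.", "H.S. .", "...", "H S 9", "A2g:50. 205.229"]:
            h.parse_specimen_reference(text)  # best effort by design
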