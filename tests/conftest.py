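import random

import pytest

import hortus as h
from hortus.blocks import BoundingBox
from hortus.segmentation import Segment, SegmentKind


@pytest.fixture(scope="session")
def clean_page():
    """One clean even page with its ground truth."""
    return h.generate_page(h.SyntheticPageSpec(seed=11))


@pytest.fixture(scope="session")
def odd_page():
    return h.generate_page(h.SyntheticPageSpec(seed=12, parity=h.Parity.ODD))


def make_segment(seg_id, kind, top, left=0.0, width=0.05, height=0.01):
    """Minimal typed segment for geometry-level tests."""
    return Segment(
        id=seg_id,
        kind=kind,
        bbox=BoundingBox(left, top, width, height),
        text="",
        word_ids=["w"],
        line_ids=["l"],
    )


def plant_at(i, top):
    return make_segment(f"plant-{i}", SegmentKind.PLANT_NAME, top)


def margin_at(i, top):
    return make_segment(f"margin-{i}", SegmentKind.MARGIN, top)


@pytest.fixture
def rng():
    return random.Random(20240901)
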