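# Methods

`hortus` mobilises structured data from word/line-level OCR block output of
digitised pages of a pre-Linnaean printed herbal index — the kind of volume
in which printed polynomial plant names are annotated by hand with
herbarium specimen references ("H.S. *volume* *folio* [*specimen*]") in the
side margins, headers and footers. The pipeline takes the block JSON that a
text-recognition service emits (PAGE/LINE/WORD blocks with fractional
bounding boxes and a PRINTED/HANDWRITING flag per word) and produces, per
page, the printed plant-name segments, the handwritten annotation segments,
and the links between them.

## Input model and coordinates

A page is a list of LINE blocks, each owning WORD blocks; every block has
an axis-aligned bounding box in page fractions (origin top-left, `Left`,
`Top`, `Width`, `Height` as ratios of the raster). The default raster is
4992 × 6668 px, so a box top at 1500 px is the fraction 1500/6668 ≈ 0.22.
Boxes are treated as closed rectangles; all fractional coordinates stay in
[0, 1] up to a provider-rounding ε of 1e-6. Orphan WORD blocks (referenced
by no LINE) are wrapped in synthetic one-word lines rather than rejected,
and low-confidence words are flagged but never dropped — degraded provider
output should flow through, with downstream consumers deciding.

All vertical reasoning uses a per-line *top* defined as the **median of
the member word-box tops** (printed words preferred), not the provider's
line box: on skewed scans the line box is inflated beyond the glyphs and
corrupts spacing measures, while word boxes stay tight. A per-page scale,
the *line pitch*, is the median gap between consecutive line tops; every
spacing threshold is a multiple of it, which makes the configuration
scale-free. The median (not minimum or mean) is used in both places for
robustness to outlier gaps and skew.

## Page structure

**Parity.** Odd and even pages carry different running titles and put the
specimen margin on opposite sides, so the page group is classified first.
Printed lines in the top 15 % of the page are matched against per-parity
title patterns after a normalisation that uppercases, maps the digit/letter
confusions 1→I and 0→O, and strips non-letters (so "H1STORIA",
"H IST OR1A" and "H I S T O R I A" all normalise to "HISTORIA"); an infix
alignment with an edit budget of 2 absorbs residual OCR damage. No match
yields UNKNOWN, which is a value, not an error.

**Layout.** The page's lines are partitioned into exactly five classes —
header band, footer band, side margin, body, and discarded bleed. The
margin boundary is found from the x-coordinates alone: word x-intervals of
mid-page lines are merged into covered segments, and the widest uncovered
gap on the parity-implied margin side (outer margin: left on even pages,
right on odd, configurable since the convention is corpus-specific), if
wider than 2 % of page width, separates the margin cluster from the body
envelope; the boundary sits at the gap midpoint. With no such gap the
boundary collapses onto the body envelope (no margin lines). Bleed — text
from the adjacent page caught at the edge of the scan — is any line lying
entirely more than 2 % outside the dominant body envelope on the
non-margin side; it is recorded and excluded from all later stages. Header
and footer bands default to the top 6 % and bottom 8 % of the page, plus
the matched running-title line wherever it sits.

## Segmentation

**Paragraphs.** Body lines are grouped top-to-bottom; a new paragraph
opens when the gap between consecutive *printed* lines exceeds
`para_gap_mult × pitch` (default 1.6). Handwritten lines inside the body
are not part of the printed flow: they are excluded from the gap signal,
and because an interruption that displaces the following printed line
would otherwise inflate the gap past the threshold, the summed box heights
of intervening handwritten lines are subtracted from the raw gap before
thresholding. The interrupting words remain members of the enclosing
paragraph, flagged handwritten, so transcription consumers can exclude
them from printed text.

**Plant names.** A paragraph is classified as a printed plant-name entry
primarily by typography: its first line is indented beyond the body-left
envelope by more than `indent_frac` (default 1.5 % of page width) and it
is short (≤ 3 lines). Entries set flush with the text fall back on lexical
features, OR-combined: an opening author abbreviation from a configurable
lexicon ("J.B.", "C.B.", "Ger.", …), a capitalised first character on a
segment of ≤ 2 lines, or all words uppercase. The OR-combination and its
precedence are one defensible reading of the feature set; the switchable
config keeps other readings available.

**Margins, headers, footers.** Margin lines are split into annotation
segments at any line whose text opens with the specimen initials (a fuzzy
"H.S." pattern accepting "H. S.", "HS", case variants) and at any gap
wider than `margin_gap_mult × pitch` (default 2.0); continuation lines of
folio numbers stay attached. Header/footer annotation segments are
contiguous *handwritten* band lines grouped by the same gap rule; printed
band lines (running title, page number) yield no segments. Specimen
references are parsed best-effort from segment text: each "H.S." anchor is
followed by the *Hortus siccus* volume number, the folio number (sometimes
"p."-prefixed in the hand), and optionally a specimen position; unparseable
spans are returned as residue, never as exceptions — handwriting
transcriptions are expected to be damaged.

## Association

Each margin annotation is linked to the plant name minimising the absolute
difference of bounding-box tops, |x − yᵢ|. The map is evaluated
independently per margin, so several annotations can legitimately share
one plant (a folio holds several specimens). Ties break toward the
smaller top — annotations are usually written beside or just below their
entry. Pages without plant names report their margins in an explicit
`unlinked` list. Header/footer annotations carry their own plant names and
are emitted as standalone records, not distance-linked. A config epsilon
can flag near-ties as ambiguous (the intersecting-annotation cases humans
also find hard); it defaults to off.

## Evaluation protocol

* **CER** = 100 × Levenshtein(gt, hyp) / |gt|, uniform edit costs, NFC
  normalisation first; may exceed 100 under heavy insertion. The distance
  is computed with edlib; an independent Wagner–Fischer DP serves as the
  oracle in the test suite.
* **Segment matching**: predicted and ground-truth segments of one page
  and category match when box IoU strictly exceeds 0.7 ("exceeded" read as
  strict, configurable); matching is greedy on descending IoU and
  one-to-one. Greedy was chosen over optimal assignment for transparency;
  a Hungarian-assignment oracle test guards the equivalence on
  well-separated instances.
* **Precision/recall/F1** per category from the matched counts, each term
  defined as 0 when its denominator is 0. A predicted (margin, plant) link
  is a true positive iff both endpoints matched ground-truth segments and
  the ground truth links those same two.
* Reports round P/R/F1 to 2 decimals and CER percentages to 1.

## Synthetic pages

The generator emits block JSON plus exact ground truth for every stage,
emulating the features the pipeline must survive: per-parity running
titles and margin sides, indented single-line plant-name entries,
3–6-line justified paragraphs at uniform pitch (0.015 of page height,
entries separated by 2× pitch), jittered "H.S." margin annotations,
handwritten header/footer annotations, adjacent-page bleed words, and
per-character transcription noise. Margin-annotation jitter is bounded at
40 % of the inter-entry spacing so the intended pairing is always the true
nearest-top argmin and the ground truth stays well-defined. Skew is
emulated exactly as the failure mode it causes: line-box heights are
inflated upward by a per-line uniform amount while word boxes stay tight,
so a line-box-based spacing ablation (exposed via `use_line_boxes`)
degrades while the word-level default does not. Generation is byte-stable
under the spec's seed.

The noise model substitutes each glyph character of a word's transcription
with an independent probability (`char_noise_rate`) by a different
character. Inter-word spaces in a segment's joined text are artifacts of
the block dialect, not glyphs, so noise calibration is checked as pooled
CER over separator-stripped text, where the binomial expectation equals
the rate; segment-level CER including separators is proportionally lower
by construction.

What the generator does **not** emulate: realistic OCR confusion
statistics (noise is uniform, real engines confuse visually similar
glyphs), font-driven error structure, multi-column layouts, curved or
rotated baselines, intersecting margin annotations, or merged/split word
boxes. Passing the recovery suite therefore shows the geometry logic is
correct under the stated layout model, not that real scans of this
difficulty reach the same scores — on real material the published range
for layouts of this kind is F1 ≈ 0.86–0.97 per category.

## Numerical choices and degenerate inputs

Thresholds all live in one frozen config: `header_frac` 0.06,
`footer_frac` 0.92, `min_margin_gap` 0.02, `bleed_frac` 0.02,
`para_gap_mult` 1.6, `margin_gap_mult` 2.0, `indent_frac` 0.015,
`max_name_lines` 3. The source material names the features (titles,
x-coordinates, spacing, indentation) but no values; these defaults are
expressed as fractions of page geometry so they transfer across scan
resolutions, and were fixed once against the generator's layout model.
Empty pages produce empty records (group UNKNOWN), not errors; pages with
fewer than two lines take a configured default pitch; a zero-area IoU
union is 0 by convention; IoU is clamped to [0, 1] against float
round-off. Corpus processing logs and counts per-page failures rather
than aborting. Test-suite problem sizes (50-page corpora, 200–1000 random
oracle instances) keep full runs in the low seconds while leaving the
binomial noise check a 3-standard-error resolution of about ±0.3
percentage points.

## Known limitations

* Confidence scores are carried through but consumed by no default stage.
* Title patterns ship for one volume family; other volumes/sections need
  pattern entries in the config.
* The margin-side-per-parity mapping is an assumption (outer margin),
  configurable but not inferable from a single page without margin words.
* Reference parsing takes at most one volume/folio/specimen triple per
  "H.S." anchor; run-on reference strings put extra numbers in the
  residue rather than guessing.
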