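"""Pipeline configuration.

Every threshold used by the layout, segmentation and association stages
lives here.  Vertical spacing thresholds are multiples of the page's line
pitch; horizontal thresholds are fractions of page width — both are
scale-free, so one config transfers between scan resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml


@dataclass(frozen=True)
class TitlePattern:
    """A running-title pattern with its page parity and edit budget."""

    parity: str  # "ODD" | "EVEN"
    pattern: str
    max_edits: int = 2


# Running titles of the two page parities.  OCR confusions (1 for I, 0 for
# O, spurious spaces) are absorbed by normalisation plus the edit budget.
DEFAULT_TITLE_PATTERNS: tuple[TitlePattern, ...] = (
    TitlePattern("EVEN", "HISTORIA PLANTARUM", 2),
    TitlePattern("EVEN", "HISTORIA", 2),
    TitlePattern("ODD", "DE HERBIS", 2),
    TitlePattern("ODD", "LIB IV", 1),
)

# Author abbreviations that open printed plant-name entries
# (e.g. Jean Bauhin, Caspar Bauhin, Gerard, Parkinson).
DEFAULT_ABBREVIATIONS: tuple[str, ...] = ("J.B.", "C.B.", "Ger.", "Park.", "Raj.", "Mor.")


@dataclass(frozen=True)
class PipelineConfig:
    # -- page structure -----------------------------------------------------
    #: Lines whose top lies above this fraction are header-band candidates.
    header_frac: float = 0.06
    #: Lines whose top lies below this fraction belong to the footer band.
    footer_frac: float = 0.92
    #: Running titles are searched in this top fraction of the page.
    title_band_frac: float = 0.15
    #: Minimum horizontal gap (fraction of width) separating the side-margin
    #: word cluster from the body envelope.
    min_margin_gap: float = 0.02
    #: A line whose box lies this far outside the body envelope on the
    #: non-margin side is discarded as bleed from the adjacent page.
    bleed_frac: float = 0.02
    #: Outer-margin convention: margin side for EVEN pages ("LEFT"/"RIGHT");
    #: ODD pages use the opposite side.
    even_margin_side: str = "LEFT"
    title_patterns: tuple[TitlePattern, ...] = DEFAULT_TITLE_PATTERNS

    # -- segmentation -------------------------------------------------------
    #: A new paragraph starts when the inter-line gap exceeds this multiple
    #: of the line pitch.
    para_gap_mult: float = 1.6
    #: A new margin/header/footer segment starts when the gap exceeds this
    #: multiple of the line pitch.
    margin_gap_mult: float = 2.0
    #: Indent (fraction of width) beyond the body-left envelope that marks
    #: a plant-name entry.
    indent_frac: float = 0.015
    #: Maximum number of lines for an indented plant-name entry.
    max_name_lines: int = 3
    #: Capitalised-first-line fallback applies up to this many lines.
    max_capital_lines: int = 2
    abbreviation_lexicon: tuple[str, ...] = DEFAULT_ABBREVIATIONS
    #: Regex matching the specimen-reference initials that open a margin
    #: annotation ("H.S." with spacing/punctuation variants).
    hs_pattern: str = r"^\s*H\s*\.?\s*S\b\s*\.?"
    #: Fall back pitch (fraction of height) for pages too short to estimate.
    default_pitch: float = 0.015
    #: Ablation switch: measure spacing from provider line boxes instead of
    #: word boxes (skew-sensitive; for evaluation only).
    use_line_boxes: bool = False

    # -- association --------------------------------------------------------
    #: When the two smallest margin-to-plant distances differ by less than
    #: this fraction, the pair is flagged ambiguous (0 disables).
    ambiguity_eps: float = 0.0
    #: Words below this confidence are flagged low-confidence (kept).
    confidence_floor: float = 0.0

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def load_config(path: str) -> PipelineConfig:
    """Load a config from YAML; absent keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    patterns = data.pop("title_patterns", None)
    cfg = PipelineConfig(**{k: v for k, v in data.items() if k != "abbreviation_lexicon"})
    if "abbreviation_lexicon" in data:
        cfg = cfg.with_overrides(abbreviation_lexicon=tuple(data["abbreviation_lexicon"]))
    if patterns is not None:
        cfg = cfg.with_overrides(
            title_patterns=tuple(
                TitlePattern(p["parity"], p["pattern"], int(p.get("max_edits", 2)))
                for p in patterns
            )
        )
    return cfg
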