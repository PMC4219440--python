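"""MNREAD-style sentence stimuli and their rasterization.

The reading test uses 60-character sentences (spaces included, 10-13
words) laid out on three lines broken as evenly as possible without
hyphenation.  The validated chart sentences are licensed content and are
not embedded; a fixture generator produces pseudo-sentences from a small
lexicon of simple words that satisfy the same structural constraints,
and a validator accepts user-supplied sentence files.

Rasterization draws white text on a black background in a Times-class
serif face, sized so that the lowercase x-height subtends exactly
``5 * 10**logMAR`` arcminutes on the display.  Because the fonts
available to the simulator are wider than the condensed chart
typesetting, glyph advances are uniformly scaled by a tracking factor
(default ``DEFAULT_TRACKING``) chosen so the whole font ladder fits the
default display; letter *size* is unaffected.  Text that still does not
fit raises :class:`StimulusOverflowError` rather than clipping.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import DisplayModel, logmar_to_xheight_deg

__all__ = [
    "SENTENCE_CHARS",
    "MIN_WORDS",
    "MAX_WORDS",
    "DEFAULT_TRACKING",
    "DEFAULT_LEXICON",
    "SentenceStimulus",
    "StimulusOverflowError",
    "generate_sentence",
    "layout_three_lines",
    "validate_sentence",
    "rasterize_sentence",
    "sentence_layout",
    "find_default_font",
]

SENTENCE_CHARS = 60
MIN_WORDS = 10
MAX_WORDS = 13

# Uniform multiplier on glyph advances.  Chosen once so that all six
# ladder sizes (1.5 .. 1.0 logMAR) of a 60-character three-line sentence
# fit a 43-deg-wide display in the bundled serif faces.
DEFAULT_TRACKING = 0.80

# Maximum typeset width of one laid-out line, in em units of the serif
# face.  Standardized reading-chart corpora are curated so every
# sentence typesets to a uniform block; the generator mirrors that by
# rejecting candidates whose widest line exceeds this budget, which is
# what keeps the largest ladder size on the default display
# (9.0 em * 262 px/em * 0.80 tracking = 1886 px < 1920 px).
MAX_LINE_WIDTH_EM = 9.0

# Simple, child-level vocabulary in the spirit of a standardized reading
# chart; lengths 2..8 so the generator can always close a sentence.
DEFAULT_LEXICON = (
    "am an as at be by do go he if in is it me my no of on so to up us we "
    "and are boy but can car cat dad day dog eat far fun get had has her "
    "him his hot mom new now old one out ran red run sat saw she sun the "
    "too two was wet you ball bird blue book came cake down farm fast "
    "find food four game girl good hand help home jump kind lake like "
    "little long look made make many milk moon more name near nice night "
    "over park play rain read ride road room school sing sleep small "
    "snow song stop story take tell that them then they this tree very "
    "walk want warm water well went were what when wide will wind with "
    "apple green happy house mother father sister friends morning yellow "
    "garden window summer winter animal basket dinner"
).split()


class StimulusOverflowError(ValueError):
    """Raised when a sentence cannot be drawn at the requested size."""


@dataclass(frozen=True)
class SentenceStimulus:
    """A reading-test sentence with its fixed three-line layout."""

    text: str
    lines: tuple[str, str, str]

    @property
    def words(self) -> list[str]:
        return self.text.split(" ")

    @property
    def char_count(self) -> int:
        return len(self.text)

    @property
    def n_words(self) -> int:
        return len(self.words)


def validate_sentence(text: str) -> list[str]:
    """Return the list of constraint violations for a candidate sentence
    (empty list means valid)."""
    problems = []
    if len(text) != SENTENCE_CHARS:
        problems.append(
            f"must be exactly {SENTENCE_CHARS} characters including spaces "
            f"(got {len(text)})"
        )
    words = text.split(" ")
    if "" in words:
        problems.append("words must be separated by single spaces")
    if not (MIN_WORDS <= len(words) <= MAX_WORDS):
        problems.append(
            f"must contain {MIN_WORDS}-{MAX_WORDS} words (got {len(words)})"
        )
    if "-" in text:
        problems.append("hyphenation is not allowed")
    return problems


def _make_sentence(text: str) -> SentenceStimulus:
    problems = validate_sentence(text)
    if problems:
        raise ValueError("; ".join(problems))
    return SentenceStimulus(text=text, lines=layout_three_lines(text.split(" ")))


@lru_cache(maxsize=4)
def _char_widths_em(font_path: str) -> dict:
    """Advance width of each lexicon character in em units."""
    from PIL import ImageFont

    em = 256
    font = ImageFont.truetype(font_path, em)
    chars = " abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return {c: font.getlength(c) / em for c in chars}


def _widest_line_em(lines, widths: dict) -> float:
    return max(sum(widths.get(c, 0.5) for c in line) for line in lines)


def generate_sentence(
    lexicon: "list[str] | None" = None, seed: int = 0
) -> SentenceStimulus:
    """Generate a pseudo-sentence satisfying the chart constraints.

    Draws words from ``lexicon`` until exactly 60 characters (spaces
    included) and 10-13 words are reached, pruning draws that would make
    the remaining length infeasible.  Candidates whose three-line layout
    typesets wider than ``MAX_LINE_WIDTH_EM`` are rejected, mirroring
    how chart corpora are curated for a uniform text block.
    Deterministic given ``seed``.
    """
    words = list(lexicon) if lexicon is not None else list(DEFAULT_LEXICON)
    if not words:
        raise ValueError("lexicon is empty")
    if any(len(w) > 10 or len(w) == 0 for w in words):
        raise ValueError("lexicon words must have lengths 1..10")
    by_len: dict[int, list[str]] = {}
    for w in words:
        by_len.setdefault(len(w), []).append(w)
    lengths = sorted(by_len)
    lo, hi = lengths[0], lengths[-1]

    rng = np.random.default_rng(seed)
    for _ in range(200):
        k = int(rng.integers(MIN_WORDS, MAX_WORDS + 1))
        need = SENTENCE_CHARS - (k - 1)  # total letters
        chosen: list[str] = []
        total = 0
        ok = True
        for slot in range(k):
            remaining_slots = k - slot - 1
            rem = need - total
            feasible = [
                n
                for n in lengths
                if remaining_slots * lo <= rem - n <= remaining_slots * hi
            ]
            if not feasible:
                ok = False
                break
            n = int(feasible[rng.integers(len(feasible))])
            pool = by_len[n]
            chosen.append(pool[int(rng.integers(len(pool)))])
            total += n
        if ok and total == need:
            text = " ".join(chosen)
            text = text[0].upper() + text[1:]
            lines = layout_three_lines(text.split(" "))
            if _widest_line_em(lines, _char_widths_em(find_default_font())) > (
                MAX_LINE_WIDTH_EM
            ):
                continue
            return _make_sentence(text)
    raise ValueError(
        "could not build a sentence from this lexicon within the search bound"
    )


def layout_three_lines(words: "list[str]") -> tuple[str, str, str]:
    """Partition words into three contiguous lines, minimizing the
    longest line's character count; ties prefer top-heavy splits."""
    k = len(words)
    if k < 3:
        raise ValueError("need at least three words for a three-line layout")
    best = None
    for i, j in itertools.combinations(range(1, k), 2):
        lines = (
            " ".join(words[:i]),
            " ".join(words[i:j]),
            " ".join(words[j:]),
        )
        lens = tuple(len(s) for s in lines)
        # minimize the max line; tie-break toward longer early lines
        key = (max(lens), -lens[0], -lens[1])
        if best is None or key < best[0]:
            best = (key, lines)
    return best[1]


def find_default_font() -> str:
    """Locate a bundled Times-class serif font file.

    Prefers STIX General (a Times-family design) from matplotlib's
    bundled fonts, falling back to DejaVu Serif.  The resolved path is a
    configuration item because glyph metrics differ between faces.
    """
    import matplotlib

    font_dir = os.path.join(
        os.path.dirname(matplotlib.__file__), "mpl-data", "fonts", "ttf"
    )
    for name in ("STIXGeneral.ttf", "DejaVuSerif.ttf"):
        path = os.path.join(font_dir, name)
        if os.path.exists(path):
            return path
    raise FileNotFoundError("no bundled serif font found")


@lru_cache(maxsize=8)
def _xheight_ratio(font_path: str) -> float:
    """Measured x-height as a fraction of the em size, from the rendered
    bitmap of a lowercase 'x' (rasterizers map font units to pixels
    differently, so the calibration is empirical)."""
    from PIL import Image, ImageDraw, ImageFont

    em = 256
    font = ImageFont.truetype(font_path, em)
    img = Image.new("L", (2 * em, 2 * em), 0)
    ImageDraw.Draw(img).text((em // 2, em // 2), "x", fill=255, font=font)
    arr = np.asarray(img)
    rows = np.where(arr.max(axis=1) > 127)[0]
    if rows.size == 0:
        raise ValueError(f"font {font_path!r} rendered an empty 'x'")
    return (rows[-1] - rows[0] + 1) / em


@dataclass(frozen=True)
class _Layout:
    em_px: int
    xheight_px: float
    ascent_px: int
    descent_px: int
    line_pitch_px: float
    line_widths_px: tuple[float, ...]
    line_lefts_px: tuple[float, ...]
    baselines_px: tuple[float, ...]
    advances: tuple[tuple[float, ...], ...]


def _layout(
    sentence: SentenceStimulus,
    size_logmar: float,
    display: DisplayModel,
    font_path: "str | None",
    tracking: float,
    line_spacing_em: float,
) -> tuple[_Layout, str]:
    from PIL import ImageFont

    path = font_path or find_default_font()
    ratio = _xheight_ratio(path)
    xheight_px = logmar_to_xheight_deg(size_logmar) * display.px_per_deg_x
    em_px = max(1, round(xheight_px / ratio))
    font = ImageFont.truetype(path, em_px)
    ascent, descent = font.getmetrics()
    pitch = line_spacing_em * em_px

    line_widths, lefts, advances = [], [], []
    for line in sentence.lines:
        adv = tuple(font.getlength(c) * tracking for c in line)
        width = sum(adv)
        if width > display.width_px:
            raise StimulusOverflowError(
                f"line {line!r} is {width:.0f} px wide at {size_logmar} logMAR "
                f"but the display is only {display.width_px} px"
            )
        line_widths.append(width)
        lefts.append((display.width_px - width) / 2.0)
        advances.append(adv)

    block_height = 2 * pitch + ascent + descent
    if block_height > display.height_px:
        raise StimulusOverflowError(
            f"three-line block is {block_height:.0f} px tall at "
            f"{size_logmar} logMAR but the display is only "
            f"{display.height_px} px"
        )
    top = (display.height_px - block_height) / 2.0
    baselines = tuple(top + ascent + i * pitch for i in range(3))
    return (
        _Layout(
            em_px=em_px,
            xheight_px=em_px * ratio,
            ascent_px=ascent,
            descent_px=descent,
            line_pitch_px=pitch,
            line_widths_px=tuple(line_widths),
            line_lefts_px=tuple(lefts),
            baselines_px=baselines,
            advances=tuple(advances),
        ),
        path,
    )


def sentence_layout(
    sentence: SentenceStimulus,
    size_logmar: float,
    display: DisplayModel | None = None,
    font_path: "str | None" = None,
    tracking: float = DEFAULT_TRACKING,
    line_spacing_em: float = 1.3,
) -> list[tuple[float, float, float]]:
    """Geometry of the three text lines as ``(x_left, x_right, y_baseline)``
    in pixels; used to program synthetic reading scanpaths."""
    display = display or DisplayModel()
    lay, _ = _layout(sentence, size_logmar, display, font_path, tracking, line_spacing_em)
    return [
        (left, left + width, baseline)
        for left, width, baseline in zip(
            lay.line_lefts_px, lay.line_widths_px, lay.baselines_px
        )
    ]


def rasterize_sentence(
    sentence: SentenceStimulus,
    size_logmar: float,
    display: DisplayModel | None = None,
    font_path: "str | None" = None,
    tracking: float = DEFAULT_TRACKING,
    line_spacing_em: float = 1.3,
) -> np.ndarray:
    """Draw the sentence as a white-on-black frame in [0, 1].

    The lowercase x-height matches the logMAR size to within a pixel;
    the three lines are horizontally centered and vertically stacked.
    Raises :class:`StimulusOverflowError` if the text cannot fit.
    """
    from PIL import Image, ImageDraw, ImageFont

    display = display or DisplayModel()
    lay, path = _layout(sentence, size_logmar, display, font_path, tracking, line_spacing_em)
    font = ImageFont.truetype(path, lay.em_px)
    img = Image.new("L", (display.width_px, display.height_px), 0)
    draw = ImageDraw.Draw(img)
    for line, left, baseline, adv in zip(
        sentence.lines, lay.line_lefts_px, lay.baselines_px, lay.advances
    ):
        x = left
        y = baseline - lay.ascent_px
        for ch, a in zip(line, adv):
            draw.text((x, y), ch, fill=255, font=font)
            x += a
    return np.asarray(img, dtype=float) / 255.0
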