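"""Tagged, styled DNA sequences.

A :class:`TaggedSequence` couples a plain DNA string with named *regions*
(0-based half-open intervals, zero-length anchors allowed) and optional
per-character display styles.  Regions are written in an XML-style
markup dialect::

    AAA<cre>CCCGGG</cre>TTT     opening/closing pair  -> region cre=[3,9)
    ACGT<ins/>ACGT              self-closing tag      -> anchor ins=[4,4)

Regions may nest properly; partial crossing is forbidden.  Region
coordinates are maintained through length-changing edits by a single
delta-shift rule (see :func:`apply_edit`), so tags placed on a source
sequence stay valid as downstream operations rewrite its content.

Styles are carried per character (not per region) so that later
annotations can overlay earlier ones attribute-wise: a mutated position
can be underlined inside a region that is already colored blue.
Rendering uses ANSI SGR escape codes.

All sequences are uppercase-canonical over the IUPAC alphabet; ambiguity
codes are permitted in source inputs only (operations that require
concrete bases check for themselves).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace as _dc_replace

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "AlphabetError",
    "TagParseError",
    "RegionError",
    "Style",
    "Region",
    "Edit",
    "TaggedSequence",
    "parse_tagged",
    "serialize_tagged",
    "apply_edit",
    "reverse_complement",
    "translate",
    "overlay_style",
    "render_ansi",
    "strip_ansi",
]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


class AlphabetError(ValueError):
    """A character outside the permitted DNA alphabet."""


class TagParseError(ValueError):
    """Malformed region markup (unmatched or crossing tags)."""


class RegionError(ValueError):
    """An interval violates region bounds or nesting rules."""


# ---------------------------------------------------------------------------
# styles


@dataclass(frozen=True)
class Style:
    """Per-character display attributes; ``None`` means "not set"."""

    fg: str | None = None
    bg: str | None = None
    bold: bool | None = None
    underline: bool | None = None

    def merged(self, other: "Style") -> "Style":
        """Overlay ``other`` on self: set attributes of ``other`` win."""
        return Style(
            fg=other.fg if other.fg is not None else self.fg,
            bg=other.bg if other.bg is not None else self.bg,
            bold=other.bold if other.bold is not None else self.bold,
            underline=other.underline if other.underline is not None else self.underline,
        )

    def is_plain(self) -> bool:
        return self.fg is None and self.bg is None and not self.bold and not self.underline


EMPTY_STYLE = Style()

# SGR code fragments for named colors; bright/extended colors use 256-color codes.
_FG_CODES = {
    "black": "30", "red": "31", "green": "32", "yellow": "33", "blue": "34",
    "magenta": "35", "cyan": "36", "white": "37", "gray": "90", "grey": "90",
    "purple": "38;5;129", "orange": "38;5;208",
}
_BG_CODES = {
    "black": "40", "red": "41", "green": "42", "yellow": "43", "blue": "44",
    "magenta": "45", "cyan": "46", "white": "47", "gray": "100", "grey": "100",
    "purple": "48;5;129", "orange": "48;5;208",
}


def as_style(value) -> Style:
    """Coerce a style spec (Style, color name, or attribute dict) to Style."""
    if value is None:
        return EMPTY_STYLE
    if isinstance(value, Style):
        return value
    if isinstance(value, str):
        if value not in _FG_CODES:
            raise ValueError(f"unknown color name {value!r}")
        return Style(fg=value)
    if isinstance(value, dict):
        return Style(**value)
    raise TypeError(f"cannot interpret {value!r} as a style")


# ---------------------------------------------------------------------------
# regions and sequences


@dataclass(frozen=True)
class Region:
    """Named half-open interval ``[start, end)``; start == end is an anchor."""

    name: str
    start: int
    end: int


@dataclass(frozen=True)
class Edit:
    """Replace ``[start, end)`` with ``replacement``.

    An empty replacement is a deletion; a zero-length target interval is
    an insertion.  The target must lie entirely inside one region or
    entirely outside all regions (no partial crossing).
    """

    start: int
    end: int
    replacement: str


@dataclass(frozen=True)
class TaggedSequence:
    """Immutable DNA string plus regions plus optional per-char styles.

    ``styles`` is either ``None`` (everything unstyled) or a tuple of
    :class:`Style`/``None`` entries with one slot per character.
    """

    chars: str
    regions: tuple[Region, ...] = ()
    styles: tuple[Style | None, ...] | None = None

    def __len__(self) -> int:
        return len(self.chars)

    def region(self, name: str) -> Region:
        """Return the unique region called ``name``."""
        hits = [r for r in self.regions if r.name == name]
        if not hits:
            names = sorted({r.name for r in self.regions})
            raise RegionError(f"no region named {name!r}; available: {names}")
        if len(hits) > 1:
            raise RegionError(f"region name {name!r} is ambiguous ({len(hits)} regions)")
        return hits[0]

    def style_at(self, i: int) -> Style:
        if self.styles is None or self.styles[i] is None:
            return EMPTY_STYLE
        return self.styles[i]


def _check_alphabet(chars: str) -> str:
    if chars != chars.upper():
        warnings.warn("lowercase sequence characters uppercased", stacklevel=3)
        chars = chars.upper()
    bad = set(chars) - set(IUPAC_CODES)
    if bad:
        raise AlphabetError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return chars


def _check_nesting(regions, length) -> None:
    for r in regions:
        if not (0 <= r.start <= r.end <= length):
            raise RegionError(f"region {r.name}=[{r.start},{r.end}) outside [0,{length}]")
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            # proper nesting or disjointness only: forbid partial crossing
            if a.start < b.start < a.end < b.end or b.start < a.start < b.end < a.end:
                raise RegionError(
                    f"regions {a.name} and {b.name} cross "
                    f"([{a.start},{a.end}) vs [{b.start},{b.end}))"
                )


def make_tagged(chars, regions=(), styles=None, *, validate=True) -> TaggedSequence:
    """Construct a TaggedSequence, validating alphabet and nesting."""
    if validate:
        chars = _check_alphabet(chars)
        _check_nesting(regions, len(chars))
        if styles is not None and len(styles) != len(chars):
            raise ValueError("styles length must equal sequence length")
    return TaggedSequence(chars, tuple(regions), styles)


# ---------------------------------------------------------------------------
# markup


_TAG_RE = re.compile(r"<(/?)([A-Za-z][A-Za-z0-9_]*)(/?)>")


def parse_tagged(text: str) -> TaggedSequence:
    """Parse XML-style region markup into a TaggedSequence.

    ``AAA<cre>CCCGGG</cre>TTT`` yields chars ``AAACCCGGGTTT`` with region
    ``cre=[3,9)``; a self-closing ``<ins/>`` yields a zero-length anchor.
    """
    chars: list[str] = []
    regions: list[Region] = []
    stack: list[tuple[str, int, int]] = []  # (name, start, text position)
    pos = 0
    for m in _TAG_RE.finditer(text):
        chars.append(text[pos:m.start()])
        pos = m.end()
        closing, name, selfclosing = m.groups()
        here = sum(map(len, chars))
        if closing and selfclosing:
            raise TagParseError(f"malformed tag {m.group(0)!r} at position {m.start()}")
        if selfclosing:
            regions.append(Region(name, here, here))
        elif closing:
            if not stack or stack[-1][0] != name:
                raise TagParseError(
                    f"unmatched closing tag </{name}> at position {m.start()}"
                )
            oname, ostart, _ = stack.pop()
            regions.append(Region(oname, ostart, here))
        else:
            stack.append((name, here, m.start()))
    if stack:
        name, _, tpos = stack[-1]
        raise TagParseError(f"unclosed tag <{name}> at position {tpos}")
    chars.append(text[pos:])
    joined = "".join(chars)
    if "<" in joined or ">" in joined:
        raise TagParseError("stray '<' or '>' outside a well-formed tag")
    # report regions in start order (ties: wider region first, i.e. outer first)
    regions.sort(key=lambda r: (r.start, -(r.end - r.start), r.name))
    return make_tagged(joined, tuple(regions))


def serialize_tagged(seq: TaggedSequence) -> str:
    """Re-emit markup; ``parse_tagged(serialize_tagged(x))`` recovers x."""
    opens: dict[int, list[Region]] = {}
    closes: dict[int, list[Region]] = {}
    anchors: dict[int, list[Region]] = {}
    for r in seq.regions:
        if r.start == r.end:
            anchors.setdefault(r.start, []).append(r)
        else:
            opens.setdefault(r.start, []).append(r)
            closes.setdefault(r.end, []).append(r)
    out = []
    for i in range(len(seq.chars) + 1):
        # close inner-first (shorter regions close before the outer ones)
        for r in sorted(closes.get(i, []), key=lambda r: (r.start, r.name), reverse=True):
            out.append(f"</{r.name}>")
        for r in anchors.get(i, []):
            out.append(f"<{r.name}/>")
        for r in sorted(opens.get(i, []), key=lambda r: (-(r.end - r.start), r.name)):
            out.append(f"<{r.name}>")
        if i < len(seq.chars):
            out.append(seq.chars[i])
    return "".join(out)


# ---------------------------------------------------------------------------
# edits


def _map_boundary(x: int, es: int, ee: int, repl_len: int, delta: int) -> int:
    if x <= es:
        return x
    if x >= ee:
        return x + delta
    # strictly inside the replaced span: clamp into the replacement
    return es + min(x - es, repl_len)


def apply_edit(seq: TaggedSequence, edit: Edit, *, style: Style | None = None) -> TaggedSequence:
    """Apply one edit, shifting every region by the documented delta rule.

    Let ``delta = len(replacement) - (end - start)``.  Region boundaries
    strictly right of the edit shift by ``delta``; a region containing
    the edit stretches by ``delta``; a zero-length anchor exactly at an
    insertion point grows to cover the inserted text.  An edit that
    partially crosses a region boundary raises :class:`RegionError`.

    Inserted characters receive ``style`` (default: unstyled).
    """
    es, ee, repl = edit.start, edit.end, edit.replacement
    if not (0 <= es <= ee <= len(seq.chars)):
        raise RegionError(f"edit [{es},{ee}) outside sequence of length {len(seq.chars)}")
    repl = _check_alphabet(repl) if repl else repl
    delta = len(repl) - (ee - es)

    new_regions = []
    for r in seq.regions:
        a, b = r.start, r.end
        # partial crossing: exactly one boundary strictly inside the edit
        if (a < es and es < b < ee) or (es < a < ee and b > ee):
            raise RegionError(
                f"edit [{es},{ee}) partially overlaps region {r.name}=[{a},{b})"
            )
        contains = (
            a <= es
            and ee <= b
            and not (b == es and a < b)   # region ends where the edit begins
            and not (a == ee and a < b)   # region begins where the edit ends
        )
        if contains:
            new_regions.append(Region(r.name, a, b + delta))
        else:
            new_regions.append(
                Region(
                    r.name,
                    _map_boundary(a, es, ee, len(repl), delta),
                    _map_boundary(b, es, ee, len(repl), delta),
                )
            )

    chars = seq.chars[:es] + repl + seq.chars[ee:]
    if seq.styles is None and style is None:
        styles = None
    else:
        base = seq.styles if seq.styles is not None else (None,) * len(seq.chars)
        styles = base[:es] + (style,) * len(repl) + base[ee:]
    return TaggedSequence(chars, tuple(new_regions), styles)


# ---------------------------------------------------------------------------
# biology helpers


def reverse_complement(seq: TaggedSequence) -> TaggedSequence:
    """Reverse-complement chars; region [a,b) maps to [L-b, L-a)."""
    chars = seq.chars.translate(_COMPLEMENT)[::-1]
    if len(chars) != len(seq.chars) or set(seq.chars) - set(IUPAC_CODES):
        raise AlphabetError("sequence contains non-complementable characters")
    L = len(seq.chars)
    regions = tuple(Region(r.name, L - r.end, L - r.start) for r in seq.regions)
    styles = None if seq.styles is None else seq.styles[::-1]
    return TaggedSequence(chars, regions, styles)


def translate(span: str) -> str:
    """Translate a DNA span with the standard genetic code ('*' = stop)."""
    if len(span) % 3 != 0:
        raise ValueError(f"span length {len(span)} is not a multiple of 3")
    bad = set(span) - set("ACGT")
    if bad:
        raise AlphabetError(f"ambiguous bases in codons: {sorted(bad)}")
    out = []
    for i in range(0, len(span), 3):
        codon = span[i:i + 3]
        out.append("*" if codon in _STOPS else _CODON_TABLE[codon])
    return "".join(out)


def overlay_style(
    seq: TaggedSequence, start: int, end: int, attrs: Style
) -> TaggedSequence:
    """Overlay ``attrs`` on characters in ``[start, end)``.

    Attributes set in ``attrs`` replace prior values on those characters;
    unset attributes persist (last-writer-wins per attribute).
    """
    if not (0 <= start <= end <= len(seq.chars)):
        raise RegionError(f"interval [{start},{end}) outside sequence")
    if attrs.is_plain() or start == end:
        return seq
    base = list(seq.styles) if seq.styles is not None else [None] * len(seq.chars)
    for i in range(start, end):
        cur = base[i] if base[i] is not None else EMPTY_STYLE
        base[i] = cur.merged(attrs)
    return TaggedSequence(seq.chars, seq.regions, tuple(base))


# ---------------------------------------------------------------------------
# rendering


_ANSI_RE = re.compile(r"\x1b\[[0-9;]*m")


def _sgr(style: Style) -> str:
    codes = []
    if style.bold:
        codes.append("1")
    if style.underline:
        codes.append("4")
    if style.fg is not None:
        codes.append(_FG_CODES[style.fg])
    if style.bg is not None:
        codes.append(_BG_CODES[style.bg])
    return ";".join(codes)


def render_ansi(seq: TaggedSequence, *, plain: bool = False) -> str:
    """Render chars with ANSI SGR styling, one escape pair per styled run.

    Stripping escape codes from the output recovers ``seq.chars`` exactly;
    with ``plain=True`` (or no styles at all) the chars are returned
    verbatim.
    """
    if plain or seq.styles is None:
        return seq.chars
    out = []
    i = 0
    n = len(seq.chars)
    while i < n:
        style = seq.styles[i] or EMPTY_STYLE
        j = i + 1
        while j < n and (seq.styles[j] or EMPTY_STYLE) == style:
            j += 1
        run = seq.chars[i:j]
        if style.is_plain():
            out.append(run)
        else:
            out.append(f"\x1b[{_sgr(style)}m{run}\x1b[0m")
        i = j
    return "".join(out)


def strip_ansi(text: str) -> str:
    """Remove ANSI SGR escape codes."""
    return _ANSI_RE.sub("", text)
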