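"""Italian grapheme segmentation and phonological feature model.

The unit of all error analysis in this package is the *grapheme*: a one- to
three-letter conversion unit of the Italian orthography.  Most Italian letters
map to a phoneme on their own, but a handful of multi-letter rules exist
(``ch``/``gh`` hard stops before front vowels, ``gn``, ``gl`` + *i*, ``sc``
before *e/i*, soft ``ci``/``gi`` with a silent *i* before *a/o/u*, and ``qu``).
Segmenting words into these units lets the error coder distinguish, say, a
failure of a multi-letter conversion rule from a plain consonant substitution.

The inventory ships as a versioned CSV rule table (``data/grapheme_rules.csv``)
holding, for each surface form: its category (vowel/consonant), its voicing
value and voicing-pair partner (p/b, t/d, c/g, f/v, s/z and the digraph pairs
ch/gh, ci/gi), its nasality flag and homorganic nasal partner (b/m, d/n), and
the identifier of the multi-letter rule that licenses it, if any.  Parsing is
deterministic: longest match, left to right, no backtracking.

Accented vowels (à è é ì ò ù) keep their surface form but share the *identity*
of their plain counterpart: in Italian the accent marks stress, not letter
identity, so error comparison is done on :attr:`Grapheme.identity`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from functools import lru_cache

__all__ = [
    "Grapheme",
    "PositionZone",
    "MalformedWordError",
    "parse_graphemes",
    "grapheme_class",
    "voicing_counterpart",
    "nasal_counterpart",
    "position_zone",
    "grapheme_inventory",
    "lookup_grapheme",
]

ACCENT_FOLD = str.maketrans("àèéìòù", "aeeiou")

#: letters accepted in input words (Italian alphabet + k + accented vowels)
LEGAL_ALPHABET = frozenset("abcdefghiklmnopqrstuvz" + "àèéìòù")

VOWELS = frozenset("aeiou")


class PositionZone(str, Enum):
    """Within-word position of an error.

    The first grapheme of a word is *exterior-left*, the last is
    *right-exterior*, anything in between is *middle*.  One-grapheme words are
    exterior-left; two-grapheme words have no middle.
    """

    EXTERIOR_LEFT = "exterior-left"
    MIDDLE = "middle"
    RIGHT_EXTERIOR = "right-exterior"


class MalformedWordError(ValueError):
    """Raised when a word contains a character outside the legal alphabet."""

    def __init__(self, text: str, position: int):
        self.text = text
        self.position = position
        super().__init__(
            f"illegal character {text[position]!r} at position {position} in {text!r}"
        )


@dataclass(frozen=True)
class Grapheme:
    """One orthographic conversion unit.

    Attributes
    ----------
    surface:
        The 1–3 character lowercase form as written.
    category:
        ``"vowel"`` or ``"consonant"``.
    voicing:
        ``"voiced"``, ``"voiceless"`` or ``"not-applicable"``.
    nasal:
        True for nasal units (m, n, gn).
    rule_id:
        Identifier of the multi-letter conversion rule that licensed this
        parse, or ``None`` for plain single-letter units.
    """

    surface: str
    category: str
    voicing: str
    nasal: bool
    rule_id: str | None = None

    @property
    def identity(self) -> str:
        """Surface with stress accents folded away (à → a); used for comparison."""
        return self.surface.translate(ACCENT_FOLD)

    def same_letter(self, other: "Grapheme") -> bool:
        return self.identity == other.identity

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.surface


@lru_cache(maxsize=1)
def grapheme_inventory() -> dict[str, Grapheme]:
    """Load the packaged rule table into a surface → Grapheme mapping."""
    table: dict[str, Grapheme] = {}
    ref = resources.files("lettura.data").joinpath("grapheme_rules.csv")
    with ref.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["surface"]] = Grapheme(
                surface=row["surface"],
                category=row["category"],
                voicing=row["voicing"],
                nasal=row["nasal"] == "1",
                rule_id=row["rule_id"] or None,
            )
    return table


@lru_cache(maxsize=1)
def _pair_tables() -> tuple[dict[str, str], dict[str, str]]:
    voicing: dict[str, str] = {}
    nasal: dict[str, str] = {}
    ref = resources.files("lettura.data").joinpath("grapheme_rules.csv")
    with ref.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row["voicing_pair"]:
                voicing[row["surface"]] = row["voicing_pair"]
            if row["nasal_pair"]:
                nasal[row["surface"]] = row["nasal_pair"]
    # nasal pairs are symmetric: b↔m, d↔n
    for a, b in list(nasal.items()):
        nasal.setdefault(b, a)
    return voicing, nasal


def lookup_grapheme(surface: str) -> Grapheme:
    """Return the inventory entry for ``surface`` (accents folded if needed)."""
    inv = grapheme_inventory()
    if surface in inv:
        return inv[surface]
    folded = surface.translate(ACCENT_FOLD)
    return inv[folded]


def parse_graphemes(text: str) -> list[Grapheme]:
    """Segment a lowercase word into graphemes.

    Longest-match, left-to-right, using the packaged rule table.  Multi-letter
    units are recognised with their licensing context: ``ch``/``gh``/``gn``/
    ``qu`` unconditionally, ``gl`` only before *i*, ``sc`` only before *e/i*,
    ``ci``/``gi`` only before another vowel (the *i* is a diacritic there).
    The concatenation of the returned surfaces always equals ``text``.

    Raises
    ------
    MalformedWordError
        If ``text`` contains a character outside the legal alphabet (the
        caller is responsible for case folding and trimming).
    """
    if not text:
        raise MalformedWordError(text or "?", 0)
    for pos, ch in enumerate(text):
        if ch not in LEGAL_ALPHABET:
            raise MalformedWordError(text, pos)

    inv = grapheme_inventory()
    out: list[Grapheme] = []
    i = 0
    n = len(text)
    while i < n:
        two = text[i : i + 2]
        nxt = text[i + 2 : i + 3].translate(ACCENT_FOLD)
        unit: str | None = None
        if two in ("ch", "gh", "gn", "qu"):
            unit = two
        elif two == "gl" and nxt == "i":
            unit = two
        elif two == "sc" and nxt in ("e", "i"):
            unit = two
        elif two in ("ci", "gi") and nxt in VOWELS:
            unit = two
        if unit is not None:
            out.append(inv[unit])
            i += 2
            continue
        ch1 = text[i]
        base = ch1.translate(ACCENT_FOLD)
        proto = inv[base]
        if ch1 == base:
            out.append(proto)
        else:  # keep accented surface, share features with the plain vowel
            out.append(
                Grapheme(ch1, proto.category, proto.voicing, proto.nasal, proto.rule_id)
            )
        i += 1
    return out


def grapheme_class(g: Grapheme) -> str:
    """Return ``"vowel"`` or ``"consonant"``."""
    return g.category


def voicing_counterpart(g: Grapheme) -> Grapheme | None:
    """The grapheme differing from ``g`` only in voicing, or None.

    Pairs: p↔b, t↔d, c↔g (k→g), f↔v, s↔z, ch↔gh, ci↔gi.  Vowels and unpaired
    consonants have no counterpart.  The relation is an involution on the
    paired inventory (``k`` maps into the c/g pair one-way).
    """
    voicing, _ = _pair_tables()
    partner = voicing.get(g.identity)
    return grapheme_inventory()[partner] if partner else None


def nasal_counterpart(g: Grapheme) -> Grapheme | None:
    """The homorganic nasality partner (b↔m, d↔n), or None."""
    _, nasal = _pair_tables()
    partner = nasal.get(g.identity)
    return grapheme_inventory()[partner] if partner else None


def position_zone(index: int, length: int) -> PositionZone:
    """Map a grapheme index to its within-word zone.

    Index 0 is exterior-left, the last index is right-exterior, everything
    else is middle.  A one-grapheme word is exterior-left.
    """
    if not 0 <= index < length:
        raise IndexError(f"grapheme index {index} out of range for length {length}")
    if index == 0:
        return PositionZone.EXTERIOR_LEFT
    if index == length - 1:
        return PositionZone.RIGHT_EXTERIOR
    return PositionZone.MIDDLE
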