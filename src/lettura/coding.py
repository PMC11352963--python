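"""Align target and response readings and emit weighted dyslexia error codes.

A child's oral reading of each battery item is transcribed orthographically
and compared with the printed target.  Every discrepancy is classified along
the dimensions that discriminate dyslexia types in a dual-route reading
model: the kind of operation (substitution, addition, omission, migration),
the unit affected (vowel, consonant, voicing or nasality feature, multi-letter
conversion rule, affix, whole word), the within-word position zone, and
whether the error could have been sourced from a neighboring printed word
(the signature of between-word, "attentional" migration).

Composite codings follow the battery's scoring convention:

* **"or" coding** — one observed discrepancy that admits up to three
  alternative explanations becomes a single *alternative group* whose codes
  share the unit weight equally (1, 1/2 or 1/3 each).
* **"and" coding** — independent discrepancies in the same word each form
  their own group of weight 1.

Weights are exact :class:`fractions.Fraction` values so that cluster scores
remain exact multiples of 1/6.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .orthography import (
    Grapheme,
    PositionZone,
    lookup_grapheme,
    nasal_counterpart,
    parse_graphemes,
    position_zone,
    voicing_counterpart,
)

__all__ = [
    "ListId",
    "Sublist",
    "ErrorType",
    "Unit",
    "Source",
    "StimulusItem",
    "ResponseRecord",
    "ErrorCode",
    "CodedResponse",
    "EditOp",
    "CodingResources",
    "CodingContext",
    "edit_script",
    "is_anagram_migration",
    "detect_neglect",
    "detect_between_word_migration",
    "detect_stress_error",
    "detect_doubling",
    "detect_semantic",
    "detect_morphological",
    "classify_response",
    "code_battery",
    "NO_RESPONSE_MARKERS",
]

NO_RESPONSE_MARKERS = frozenset({"", "-", "--", "?", "non so", "nonso"})

#: default affix inventory for morphological-error detection
DEFAULT_PREFIXES = ("pre", "ri", "dis", "con", "in", "s")
DEFAULT_SUFFIXES = ("mente", "issimo", "etto", "ino")


class ListId(str, Enum):
    WORD = "word"
    STRESS = "stress"
    PAIRS = "pairs"
    NONWORD = "nonword"


class Sublist(str, Enum):
    MIGRATABLE = "migratable"
    NEGLECT = "neglect"
    VOWEL_NEIGHBOR = "vowel-neighbor"
    FUNCTION_ABSTRACT = "function-abstract"
    SYNONYM_PRONE = "synonym-prone"
    STRESS_ITEM = "stress-item"
    PAIR_MEMBER = "pair-member"
    PLAIN_NONWORD = "plain-nonword"


class ErrorType(str, Enum):
    SUBSTITUTION = "substitution"
    ADDITION = "addition"
    OMISSION = "omission"
    WITHIN_WORD_MIGRATION = "within-word-migration"
    BETWEEN_WORD_MIGRATION = "between-word-migration"
    DOUBLING = "doubling"
    DOUBLING_OMISSION = "doubling-omission"
    STRESS_SHIFT = "stress-shift"
    NEGLECT_LEFT = "neglect-left"
    SEMANTIC = "semantic"
    MORPHOLOGICAL = "morphological"
    NO_RESPONSE = "no-response"


class Unit(str, Enum):
    VOWEL = "vowel"
    CONSONANT = "consonant"
    VOICING_FEATURE = "voicing-feature"
    NASALITY_FEATURE = "nasality-feature"
    MULTI_LETTER_RULE = "multi-letter-rule"
    AFFIX = "affix"
    WHOLE_WORD = "whole-word"
    NOT_APPLICABLE = "not-applicable"


class Source(str, Enum):
    NONE = "none"
    HORIZONTAL = "horizontal-neighbor"
    VERTICAL = "vertical-neighbor"


@dataclass(frozen=True)
class StimulusItem:
    """One battery item with its sensitivity tags and sheet position."""

    item_id: str
    text: str
    list_id: ListId
    sublist: Sublist
    stress_syllable: int | None = None
    line_index: int = 0
    pair_partner: str | None = None

    def __post_init__(self) -> None:
        if (self.stress_syllable is not None) != (self.list_id == ListId.STRESS):
            raise ValueError(
                f"{self.item_id}: stress_syllable is required exactly for stress-list items"
            )
        if (self.pair_partner is not None) != (self.list_id == ListId.PAIRS):
            raise ValueError(
                f"{self.item_id}: pair_partner is required exactly for pairs-list items"
            )


@dataclass(frozen=True)
class ResponseRecord:
    """One transcribed response (verbatim, including later-corrected errors)."""

    child_id: str
    grade: int
    item_id: str
    response_text: str
    response_stress: int | None = None
    self_corrected: bool = False

    def __post_init__(self) -> None:
        if not 2 <= self.grade <= 8:
            raise ValueError(f"grade must be in 2..8, got {self.grade}")


@dataclass(frozen=True)
class ErrorCode:
    """One classified reading error."""

    etype: ErrorType
    unit: Unit
    position: PositionZone | None = None
    source: Source = Source.NONE
    lexicalized: bool = False
    weight: Fraction = Fraction(1)
    detail: str = ""

    def __post_init__(self) -> None:
        if self.weight not in (Fraction(1), Fraction(1, 2), Fraction(1, 3)):
            raise ValueError(f"weight must be 1, 1/2 or 1/3, got {self.weight}")
        if self.etype == ErrorType.BETWEEN_WORD_MIGRATION and self.source == Source.NONE:
            raise ValueError("between-word migration requires a neighbor source")


@dataclass(frozen=True)
class CodedResponse:
    """All error codes for one (item, child) pair.

    ``groups`` is a tuple of alternative groups: codes within a group are
    "or" alternatives sharing weight (summing to 1); distinct groups are
    co-occurring "and" errors.
    """

    item_id: str
    child_id: str
    groups: tuple[tuple[ErrorCode, ...], ...]
    self_corrected: bool = False

    @property
    def is_correct(self) -> bool:
        return not self.groups

    def all_codes(self) -> Iterable[ErrorCode]:
        for group in self.groups:
            yield from group


# ---------------------------------------------------------------------------
# edit script
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditOp:
    """One operation transforming target toward response.

    ``index`` is the position in the partially-transformed string, whose
    prefix up to ``index`` already matches the response — so for
    substitutions and insertions it is also the response index.
    ``src_index`` is set for moves (origin of the moved grapheme).
    """

    op: str  # substitute | insert | delete | move
    index: int
    old: str | None = None  # identity removed/replaced
    new: str | None = None  # identity inserted/resulting
    src_index: int | None = None


def _identities(seq: Sequence[Grapheme]) -> tuple[str, ...]:
    return tuple(g.identity for g in seq)


def edit_script(
    target: Sequence[Grapheme], response: Sequence[Grapheme]
) -> list[EditOp]:
    """Minimal edit script under unit costs with single-grapheme moves.

    Operations: substitute, insert, delete, and move (adjacent or not) — each
    of cost 1.  The script is found by uniform-cost search that always repairs
    the leftmost mismatch, expanding moves before substitutions before
    deletions before insertions, which makes ties resolve toward moves and
    leftmost edits deterministically.
    """
    start = _identities(target)
    goal = _identities(response)
    if start == goal:
        return []
    counter = 0
    heap: list[tuple[int, int, tuple[str, ...], tuple[EditOp, ...]]] = [
        (0, 0, start, ())
    ]
    best: dict[tuple[str, ...], int] = {start: 0}
    while heap:
        cost, _, cur, script = heapq.heappop(heap)
        if cur == goal:
            return list(script)
        if cost > best.get(cur, cost):
            continue
        # leftmost mismatch
        i = 0
        while i < len(cur) and i < len(goal) and cur[i] == goal[i]:
            i += 1
        succ: list[tuple[tuple[str, ...], EditOp]] = []
        if i < len(goal):
            # move a later grapheme into place
            for j in range(i + 1, len(cur)):
                if cur[j] == goal[i]:
                    moved = cur[:i] + (cur[j],) + cur[i:j] + cur[j + 1 :]
                    succ.append(
                        (moved, EditOp("move", i, new=cur[j], src_index=j))
                    )
        if i < len(cur):
            # or move the mismatched grapheme rightward out of the way
            rest = cur[:i] + cur[i + 1 :]
            for p in range(i + 1, len(rest) + 1):
                moved = rest[:p] + (cur[i],) + rest[p:]
                succ.append((moved, EditOp("move", p, new=cur[i], src_index=i)))
        if i < len(cur) and i < len(goal):
            succ.append(
                (
                    cur[:i] + (goal[i],) + cur[i + 1 :],
                    EditOp("substitute", i, old=cur[i], new=goal[i]),
                )
            )
        if i < len(cur):
            succ.append((cur[:i] + cur[i + 1 :], EditOp("delete", i, old=cur[i])))
        if i < len(goal):
            succ.append(
                (cur[:i] + (goal[i],) + cur[i:], EditOp("insert", i, new=goal[i]))
            )
        for nxt, op in succ:
            ncost = cost + 1
            if ncost < best.get(nxt, ncost + 1):
                best[nxt] = ncost
                counter += 1
                heapq.heappush(heap, (ncost, counter, nxt, script + (op,)))
    raise RuntimeError("edit search exhausted without reaching the response")


def is_anagram_migration(
    target: Sequence[Grapheme], response: Sequence[Grapheme]
) -> tuple[bool, list[int]]:
    """True iff target and response are distinct orderings of the same graphemes.

    Returns the displaced indices (positions where the sequences disagree).
    """
    t, r = _identities(target), _identities(response)
    if t == r or sorted(t) != sorted(r):
        return False, []
    return True, [i for i, (a, b) in enumerate(zip(t, r)) if a != b]


# ---------------------------------------------------------------------------
# specialised detectors
# ---------------------------------------------------------------------------


def _in_lexicon(word: str, lexicon) -> bool:
    return lexicon is not None and word in lexicon


def detect_neglect(
    target: Sequence[Grapheme],
    response: Sequence[Grapheme],
    lexicon=None,
    side: str = "left",
) -> ErrorCode | None:
    """Left-side neglect pattern: a contiguous left prefix omitted or replaced.

    Omission: the response equals the target minus a left prefix of >= 1
    grapheme (convento -> vento).  Substitution: same length, the shared
    suffix is intact and >= 2 left graphemes differ (a single initial-letter
    substitution carries no side signature and is left to the general coder).
    The mirrored right-side variant is available via ``side="right"``.
    """
    t, r = _identities(target), _identities(response)
    if side == "right":
        t, r = t[::-1], r[::-1]
    if t == r or not r:
        return None
    etype = ErrorType.NEGLECT_LEFT
    zone = PositionZone.EXTERIOR_LEFT if side == "left" else PositionZone.RIGHT_EXTERIOR
    lexicalized = _in_lexicon("".join(g.surface for g in response), lexicon)
    k = len(t) - len(r)
    if k >= 1 and t[k:] == r:
        return ErrorCode(etype, Unit.WHOLE_WORD, zone, lexicalized=lexicalized,
                         detail=f"omitted-prefix:{k}")
    if len(t) == len(r):
        # smallest k with matching suffix; all of t[:k] vs r[:k] must differ
        for k in range(2, len(t)):
            if t[k:] == r[k:] and all(a != b for a, b in zip(t[:k], r[:k])):
                return ErrorCode(etype, Unit.WHOLE_WORD, zone,
                                 lexicalized=lexicalized,
                                 detail=f"substituted-prefix:{k}")
    return None


def detect_doubling(
    target: Sequence[Grapheme], response: Sequence[Grapheme]
) -> ErrorCode | None:
    """Doubling of a single grapheme, or degemination of a doubled one."""
    t, r = _identities(target), _identities(response)
    if len(r) == len(t) + 1:
        long, short, etype = r, t, ErrorType.DOUBLING
    elif len(t) == len(r) + 1:
        long, short, etype = t, r, ErrorType.DOUBLING_OMISSION
    else:
        return None
    for i in range(len(long)):
        if long[:i] + long[i + 1 :] == tuple(short):
            doubled = (i > 0 and long[i - 1] == long[i]) or (
                i + 1 < len(long) and long[i + 1] == long[i]
            )
            if doubled:
                g = lookup_grapheme(long[i])
                unit = Unit.VOWEL if g.category == "vowel" else Unit.CONSONANT
                zone = position_zone(min(i, len(target) - 1), len(target))
                return ErrorCode(etype, unit, zone, detail=f"letter:{long[i]}")
    return None


def detect_stress_error(
    item: StimulusItem, response_stress: int | None, segmental_ok: bool
) -> ErrorCode | None:
    """Stress-position error on a stress-list item read segmentally correctly.

    Nonwords never yield stress codes: both penultimate and antepenultimate
    stress are legitimate readings of a letter string with no lexical entry.
    """
    if item.list_id != ListId.STRESS:
        return None
    if not segmental_ok or response_stress is None:
        return None
    if response_stress != item.stress_syllable:
        return ErrorCode(
            ErrorType.STRESS_SHIFT,
            Unit.NOT_APPLICABLE,
            None,
            detail=f"stress:{item.stress_syllable}->{response_stress}",
        )
    return None


def detect_semantic(
    target_text: str,
    response_text: str,
    semantic_table: Iterable[tuple[str, str]] | None,
    lexicon=None,
) -> ErrorCode | None:
    """Whole-word semantic substitution (circa -> quasi, selva -> bosco).

    The pair must appear in the configured synonym/semantic-relatedness
    table.  When the response also admits a compact letter-level reading
    (edit distance <= 2) and at least half of its letters occur in the
    target, the visual explanation prevails and no semantic code is given.
    """
    if semantic_table is None or (target_text, response_text) not in set(semantic_table):
        return None
    t = parse_graphemes(target_text)
    r = parse_graphemes(response_text)
    overlap = sum(1 for g in r if g.identity in {x.identity for x in t})
    if overlap * 2 >= len(r) and len(edit_script(t, r)) <= 2:
        return None
    return ErrorCode(
        ErrorType.SEMANTIC,
        Unit.WHOLE_WORD,
        None,
        lexicalized=_in_lexicon(response_text, lexicon),
        detail=f"semantic:{response_text}",
    )


def _strip_affix(ids: tuple[str, ...], prefixes, suffixes):
    """Yield (stem, affix) readings of an identity tuple."""
    word = "".join(ids)
    yield word, None
    for p in prefixes:
        if word.startswith(p) and len(word) - len(p) >= 3:
            yield word[len(p):], f"pre:{p}"
    for s in suffixes:
        if word.endswith(s) and len(word) - len(s) >= 3:
            yield word[: -len(s)], f"suf:{s}"


def detect_morphological(
    target: Sequence[Grapheme],
    response: Sequence[Grapheme],
    prefixes: Sequence[str] = DEFAULT_PREFIXES,
    suffixes: Sequence[str] = DEFAULT_SUFFIXES,
) -> ErrorCode | None:
    """Affix substitution/addition/omission over a shared stem.

    premettere -> mettere is a prefix omission; the anagram path handles
    transposition words (corpo -> copro) before this detector is consulted.
    """
    t, r = _identities(target), _identities(response)
    if t == r:
        return None
    for t_stem, t_affix in _strip_affix(t, prefixes, suffixes):
        for r_stem, r_affix in _strip_affix(r, prefixes, suffixes):
            if t_affix is None and r_affix is None:
                continue
            if t_stem == r_stem:
                if t_affix and r_affix:
                    kind = ErrorType.SUBSTITUTION
                elif t_affix:
                    kind = ErrorType.OMISSION
                else:
                    kind = ErrorType.ADDITION
                zone = (
                    PositionZone.EXTERIOR_LEFT
                    if "pre:" in (t_affix or r_affix or "")
                    else PositionZone.RIGHT_EXTERIOR
                )
                return ErrorCode(
                    ErrorType.MORPHOLOGICAL,
                    Unit.AFFIX,
                    zone,
                    detail=f"{kind.value}:{t_affix or ''}->{r_affix or ''}",
                )
    return None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class CodingResources:
    """Shared lookup resources for classification.

    ``lexicon`` is anything supporting ``in`` over lowercase words (a set, a
    dict, or :class:`lettura.synthesis.Lexicon`); ``semantic_table`` is a set
    of (target, response) pairs; the affix inventory is configurable.
    ``vowel_migrations_feed_vowel`` controls whether vowel migrations also
    count toward the Vowel cluster (handled downstream in scoring).
    """

    lexicon: object | None = None
    semantic_table: set[tuple[str, str]] = field(default_factory=set)
    prefixes: tuple[str, ...] = DEFAULT_PREFIXES
    suffixes: tuple[str, ...] = DEFAULT_SUFFIXES
    max_alternatives: int = 3


@dataclass
class CodingContext:
    """Printed neighborhood of an item: its horizontal pair partner and the
    item texts on the lines immediately above and below in the same list."""

    partner_text: str | None = None
    above_text: str | None = None
    below_text: str | None = None

    def neighbors(self) -> list[tuple[str, Source]]:
        out = []
        if self.partner_text:
            out.append((self.partner_text, Source.HORIZONTAL))
        for text in (self.above_text, self.below_text):
            if text:
                out.append((text, Source.VERTICAL))
        return out


def _unit_for(g: Grapheme) -> Unit:
    if g.rule_id is not None:
        return Unit.MULTI_LETTER_RULE
    return Unit.VOWEL if g.category == "vowel" else Unit.CONSONANT


def _plain_code(op: EditOp, target, response, lexicalized: bool) -> ErrorCode:
    if op.op == "substitute":
        old, new = lookup_grapheme(op.old), lookup_grapheme(op.new)
        vc = voicing_counterpart(old)
        nc = nasal_counterpart(old)
        if vc is not None and vc.identity == new.identity:
            unit = Unit.VOICING_FEATURE
        elif nc is not None and nc.identity == new.identity:
            unit = Unit.NASALITY_FEATURE
        elif old.rule_id is not None or new.rule_id is not None:
            unit = Unit.MULTI_LETTER_RULE
        else:
            unit = _unit_for(old)
        zone = position_zone(min(op.index, len(response) - 1), len(response))
        return ErrorCode(ErrorType.SUBSTITUTION, unit, zone, lexicalized=lexicalized,
                         detail=f"{op.old}->{op.new}")
    if op.op == "insert":
        g = lookup_grapheme(op.new)
        zone = position_zone(min(op.index, len(response) - 1), len(response))
        return ErrorCode(ErrorType.ADDITION, _unit_for(g), zone,
                         lexicalized=lexicalized, detail=f"+{op.new}")
    if op.op == "delete":
        g = lookup_grapheme(op.old)
        zone = position_zone(min(op.index, len(target) - 1), len(target))
        return ErrorCode(ErrorType.OMISSION, _unit_for(g), zone,
                         lexicalized=lexicalized, detail=f"-{op.old}")
    # move: a within-word migration surfacing inside a mixed edit script
    g = lookup_grapheme(op.new)
    zone = position_zone(min(op.index, len(response) - 1), len(response))
    return ErrorCode(ErrorType.WITHIN_WORD_MIGRATION, _unit_for(g), zone,
                     lexicalized=lexicalized, detail=f"move:{op.new}")


def _doubling_refinement(op: EditOp, target, response) -> ErrorCode | None:
    """Relabel an insert/delete that duplicates or degeminates a neighbor."""
    if op.op == "delete":
        t = _identities(target)
        i = op.index
        # deletion inside a doubled pair of the target
        for j in range(len(t)):
            if t[j] == op.old and (
                (j > 0 and t[j - 1] == op.old) or (j + 1 < len(t) and t[j + 1] == op.old)
            ):
                g = lookup_grapheme(op.old)
                unit = Unit.VOWEL if g.category == "vowel" else Unit.CONSONANT
                zone = position_zone(min(i, len(target) - 1), len(target))
                return ErrorCode(ErrorType.DOUBLING_OMISSION, unit, zone,
                                 detail=f"letter:{op.old}")
    elif op.op == "insert":
        r = _identities(response)
        i = op.index
        if (i > 0 and r[i - 1] == op.new) or (i + 1 < len(r) and r[i + 1] == op.new):
            g = lookup_grapheme(op.new)
            unit = Unit.VOWEL if g.category == "vowel" else Unit.CONSONANT
            zone = position_zone(min(i, len(response) - 1), len(response))
            return ErrorCode(ErrorType.DOUBLING, unit, zone, detail=f"letter:{op.new}")
    return None


def _neighbor_migration(
    op: EditOp, response, context: CodingContext | None, lexicalized: bool
) -> ErrorCode | None:
    """Between-word migration candidate for a substitution/insertion op.

    The discrepant response grapheme must match a neighbor's grapheme at the
    same within-word position (position-preserving migration); neighbors are
    the horizontal pair partner and the items printed directly above/below.
    """
    if context is None or op.op not in ("substitute", "insert"):
        return None
    for text, source in context.neighbors():
        nb = _identities(parse_graphemes(text))
        if op.index < len(nb) and nb[op.index] == op.new:
            g = lookup_grapheme(op.new)
            zone = position_zone(min(op.index, len(response) - 1), len(response))
            return ErrorCode(
                ErrorType.BETWEEN_WORD_MIGRATION, _unit_for(g), zone,
                source=source, lexicalized=lexicalized,
                detail=f"from:{text}@{op.index}",
            )
    return None


def detect_between_word_migration(
    targets: Sequence[str], responses: Sequence[str]
) -> list[ErrorCode]:
    """Between-word migration codes for a row of neighboring items.

    For each (target, response) pair, the other members of the row act as
    horizontal neighbors.  Used standalone for pairs-list rows; the full
    classifier applies the same matching with vertical neighbors as well.
    """
    out: list[ErrorCode] = []
    for i, (t_text, r_text) in enumerate(zip(targets, responses)):
        t, r = parse_graphemes(t_text), parse_graphemes(r_text)
        if _identities(t) == _identities(r):
            continue
        others = [targets[j] for j in range(len(targets)) if j != i]
        ctx = CodingContext(partner_text=others[0] if others else None)
        for op in edit_script(t, r):
            code = _neighbor_migration(op, r, ctx, False)
            if code is not None:
                out.append(code)
    return out


_WHOLE_WORD_PRECEDENCE = (
    ErrorType.NEGLECT_LEFT,
    ErrorType.SEMANTIC,
    ErrorType.MORPHOLOGICAL,
)


def classify_response(
    item: StimulusItem,
    record: ResponseRecord,
    context: CodingContext | None = None,
    resources: CodingResources | None = None,
) -> CodedResponse:
    """Classify one response into weighted alternative groups.

    Pipeline: a missing response is one whole-word no-response code; a
    segmentally correct response can only carry a stress-shift; an anagram
    response is coded as within-word migration(s); otherwise whole-word
    detectors (neglect, semantic, morphological) that explain the entire
    discrepancy compete as "or" alternatives, and failing those the minimal
    edit script is coded operation by operation, with doubling refinement,
    featural unit labels and between-word migration alternatives from the
    printed neighborhood.
    """
    if resources is None:
        resources = CodingResources()
    if record.item_id != item.item_id:
        raise ValueError(f"response {record.item_id!r} does not match item {item.item_id!r}")

    text = record.response_text.strip().lower()
    if text in NO_RESPONSE_MARKERS:
        return CodedResponse(
            item.item_id,
            record.child_id,
            ((ErrorCode(ErrorType.NO_RESPONSE, Unit.WHOLE_WORD),),),
            record.self_corrected,
        )

    target = parse_graphemes(item.text.strip().lower())
    response = parse_graphemes(text)
    segmental_ok = _identities(target) == _identities(response)
    lexicalized = (
        not segmental_ok
        and item.list_id != ListId.PAIRS
        and _in_lexicon(text, resources.lexicon)
    )

    groups: list[tuple[ErrorCode, ...]] = []
    if not segmental_ok:
        anagram, _moved = is_anagram_migration(target, response)
        if anagram:
            for op in edit_script(target, response):
                code = _plain_code(op, target, response, lexicalized)
                groups.append((replace(code, etype=ErrorType.WITHIN_WORD_MIGRATION),)
                              if code.etype != ErrorType.WITHIN_WORD_MIGRATION
                              else (code,))
        else:
            whole: list[ErrorCode] = []
            neglect = detect_neglect(target, response, resources.lexicon)
            if neglect is not None:
                whole.append(neglect)
            semantic = detect_semantic(
                item.text.strip().lower(), text, resources.semantic_table,
                resources.lexicon,
            )
            if semantic is not None:
                whole.append(semantic)
            morph = detect_morphological(
                target, response, resources.prefixes, resources.suffixes
            )
            if morph is not None:
                whole.append(morph)
            if whole:
                whole.sort(key=lambda c: _WHOLE_WORD_PRECEDENCE.index(c.etype))
                whole = whole[: resources.max_alternatives]
                w = Fraction(1, len(whole))
                groups.append(tuple(
                    replace(c, lexicalized=lexicalized or c.lexicalized, weight=w)
                    for c in whole
                ))
            else:
                for op in edit_script(target, response):
                    alts: list[ErrorCode] = []
                    migration = _neighbor_migration(op, response, context, lexicalized)
                    doubling = _doubling_refinement(op, target, response)
                    if (
                        migration is not None
                        and op.op == "substitute"
                        and migration.source == Source.HORIZONTAL
                    ):
                        # a position-preserving exchange with the printed pair
                        # partner is the between-word migration signature
                        # itself; a vertical coincidence stays ambiguous and
                        # joins the letter-level reading as an alternative
                        alts = [migration]
                    else:
                        if migration is not None:
                            alts.append(migration)
                        if doubling is not None:
                            alts.append(replace(doubling, lexicalized=lexicalized))
                        else:
                            alts.append(_plain_code(op, target, response, lexicalized))
                    alts = alts[: resources.max_alternatives]
                    w = Fraction(1, len(alts))
                    groups.append(tuple(replace(c, weight=w) for c in alts))

    stress = detect_stress_error(item, record.response_stress, segmental_ok)
    if stress is not None:
        groups.append((stress,))

    return CodedResponse(item.item_id, record.child_id, tuple(groups),
                         record.self_corrected)


def code_battery(
    items: Sequence[StimulusItem],
    records: Sequence[ResponseRecord],
    resources: CodingResources | None = None,
) -> list[CodedResponse]:
    """Classify a child's (or cohort's) full response set against a battery.

    Builds each item's printed neighborhood (pair partner, lines above and
    below within the same list) automatically from ``line_index``.
    """
    by_id: dict[str, StimulusItem] = {}
    for it in items:
        if it.item_id in by_id:
            raise ValueError(f"duplicate item_id {it.item_id!r}")
        by_id[it.item_id] = it
    by_line: dict[tuple[ListId, int], list[StimulusItem]] = {}
    for it in items:
        by_line.setdefault((it.list_id, it.line_index), []).append(it)

    responded = {(r.child_id, r.item_id) for r in records}
    out: list[CodedResponse] = []
    for rec in records:
        item = by_id.get(rec.item_id)
        if item is None:
            raise KeyError(f"unknown item_id {rec.item_id!r}")
        partner = None
        if item.pair_partner is not None:
            if item.pair_partner not in by_id:
                raise KeyError(
                    f"item {item.item_id!r} names missing partner {item.pair_partner!r}"
                )
            if (rec.child_id, item.pair_partner) not in responded:
                raise ValueError(
                    f"pairs-list item {item.item_id!r} coded without its "
                    f"partner's response for child {rec.child_id!r}"
                )
            partner = by_id[item.pair_partner].text
        above = _line_text(by_line, item, -1)
        below = _line_text(by_line, item, +1)
        ctx = CodingContext(partner_text=partner, above_text=above, below_text=below)
        out.append(classify_response(item, rec, ctx, resources))
    return out


def _line_text(by_line, item: StimulusItem, delta: int) -> str | None:
    neighbors = by_line.get((item.list_id, item.line_index + delta))
    if not neighbors:
        return None
    # align on column: same position within the line
    row = by_line[(item.list_id, item.line_index)]
    col = row.index(item)
    return neighbors[min(col, len(neighbors) - 1)].text
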