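"""Synthetic lexicon, stimulus construction and simulated readers.

The screening battery's stimuli are not arbitrary words: every sublist is
*sensitive* to one dyslexia type because an error of that type on the item
tends to produce another existing word.  This module implements the
construction algorithms over any frequency-annotated lexicon — finding
anagram (migratable) words, exchange-migratable word pairs, left-embedded
("neglect") carriers and vowel-neighborhood nonwords — plus a seeded
generator of an Italian-like lexicon that guarantees those structures by
construction, so the whole pipeline is testable without child data or the
proprietary corpora.

The synthetic lexicon uses CV phonotactics with final vowels and Zipf-like
frequencies.  Its consonant inventory deliberately avoids the letters that
trigger multi-letter conversion rules (c, g, s, h, q), so that letter-level
and grapheme-level operations coincide in simulations; it makes no claim of
lexical validity, and real corpora can be plugged in through the same
:class:`Lexicon` interface.

Simulated readers invert the error taxonomy: a reader profile holds one
per-opportunity probability per dyslexia type, and each sensitive item is
answered either correctly or with that type's signature error (anagram
transposition, position-preserving between-word exchange, lexicalizing
vowel substitution, voicing flip, stress shift, doubling change).  Simulated
cohorts draw per-cluster error counts from a negative binomial matched to a
norm cell's mean and SD (Poisson when not overdispersed), for calibration of
the flagging procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .coding import ListId, ResponseRecord, StimulusItem, Sublist
from .norming import NormTable
from .scoring import ClusterScore

__all__ = [
    "Lexicon",
    "ReaderProfile",
    "Battery",
    "LexiconShortfallError",
    "synth_lexicon",
    "find_migratable_words",
    "find_migratable_pairs",
    "find_neglect_items",
    "vowel_neighbor_nonwords",
    "assemble_battery",
    "simulate_reader",
    "simulate_cohort",
    "DEFAULT_COMPOSITION",
]

_VOWELS = "aeiou"
#: consonants that never open a multi-letter conversion site
_CONSONANTS = "bdflmnprtvz"
_VOICING_FLIP = {"p": "b", "b": "p", "t": "d", "d": "t", "f": "v", "v": "f"}


class Lexicon:
    """A word → frequency-per-million mapping with membership lookup."""

    def __init__(self, entries: dict[str, float],
                 child_frequencies: dict[str, float] | None = None):
        for w, f in entries.items():
            if f < 0:
                raise ValueError(f"negative frequency for {w!r}")
        self.entries = dict(entries)
        self.child_frequencies = dict(child_frequencies or {})

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def frequency(self, word: str) -> float:
        return self.entries[word]

    @property
    def alphabet(self) -> set[str]:
        return set("".join(self.entries))

    def words(self) -> list[str]:
        return sorted(self.entries)


class LexiconShortfallError(ValueError):
    """Raised when a lexicon cannot fill the battery's sublist quotas."""

    def __init__(self, shortfalls: dict[str, tuple[int, int]]):
        self.shortfalls = shortfalls
        msg = "; ".join(
            f"{k}: need {need}, found {got}" for k, (need, got) in shortfalls.items()
        )
        super().__init__(f"lexicon cannot fill battery quotas ({msg})")


# ---------------------------------------------------------------------------
# synthetic lexicon
# ---------------------------------------------------------------------------


def _cv_word(rng: np.random.Generator, syllables: int) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(syllables)
    )


def synth_lexicon(
    seed: int,
    size: int = 1200,
    anagram_pairs: int = 30,
    exchange_quads: int = 30,
    neglect_carriers: int = 50,
    vowel_pairs: int = 70,
    trisyllabic: int = 60,
) -> Lexicon:
    """Generate a seeded Italian-like lexicon with guaranteed structures.

    Quotas are met by construction: ``anagram_pairs`` word pairs related by
    an adjacent middle-consonant transposition (the lardo/ladro pattern),
    ``exchange_quads`` four-word families closed under a position-preserving
    first-letter exchange (the cena/pera/pena/cera pattern, two shared
    vowels), ``neglect_carriers`` long words embedding a shorter lexicon
    word after a >= 2-letter left prefix, ``vowel_pairs`` pairs differing in
    one middle vowel, and ``trisyllabic`` plain CVCVCV words for the stress
    list; the remainder is disyllabic/trisyllabic CV filler.  Frequencies
    are Zipf-like (per million) over a random rank permutation.
    """
    if size < 100:
        raise ValueError("size must be >= 100")
    rng = np.random.default_rng(seed)
    words: dict[str, str] = {}  # word -> construction tag

    def add(word: str, tag: str) -> bool:
        if word in words:
            return False
        words[word] = tag
        return True

    made = 0
    while made < anagram_pairs:
        c1, c2, c3 = rng.choice(list(_CONSONANTS), 3, replace=False)
        v1, v2 = rng.choice(list(_VOWELS), 2, replace=False)
        w1 = f"{c1}{v1}{c2}{c3}{v2}"
        w2 = f"{c1}{v1}{c3}{c2}{v2}"
        if w1 not in words and w2 not in words:
            add(w1, "anagram")
            add(w2, "anagram")
            made += 1

    made = 0
    while made < exchange_quads:
        c1, c2, c3, c4 = rng.choice(list(_CONSONANTS), 4, replace=False)
        v1, v2 = rng.choice(list(_VOWELS), 2, replace=False)
        quad = [f"{a}{v1}{b}{v2}" for a, b in
                ((c1, c2), (c3, c4), (c3, c2), (c1, c4))]
        if all(w not in words for w in quad):
            for w in quad:
                add(w, "exchange")
            made += 1

    made = 0
    while made < neglect_carriers:
        base = _cv_word(rng, int(rng.integers(2, 4)))
        prefix = _cv_word(rng, 1) + (rng.choice(list(_CONSONANTS)) if rng.random() < 0.3 else "")
        carrier = prefix + base
        if len(carrier) <= 9 and base not in words and carrier not in words:
            add(base, "embedded-base")
            add(carrier, "neglect-carrier")
            made += 1

    made = 0
    while made < vowel_pairs:
        w = _cv_word(rng, 3)
        pos = int(rng.choice([1, 3]))  # a middle vowel slot of CVCVCV
        alt = rng.choice([v for v in _VOWELS if v != w[pos]])
        w2 = w[:pos] + alt + w[pos + 1 :]
        if w not in words and w2 not in words:
            add(w, "vowel-pair")
            add(w2, "vowel-pair")
            made += 1

    made = 0
    while made < trisyllabic:
        w = _cv_word(rng, 3)
        if add(w, "trisyllabic"):
            made += 1

    while len(words) < size:
        syl = int(rng.choice([2, 3, 3, 4], p=[0.35, 0.3, 0.3, 0.05]))
        w = _cv_word(rng, syl)
        add(w, "filler")

    ordered = list(words)
    ranks = rng.permutation(len(ordered))
    entries = {
        w: round(1000.0 / (1 + int(r)) ** 1.05, 4) for w, r in zip(ordered, ranks)
    }
    return Lexicon(entries)


# ---------------------------------------------------------------------------
# stimulus-construction searches
# ---------------------------------------------------------------------------


def _is_middle_transposition(w1: str, w2: str) -> bool:
    """True when w2 is w1 with two adjacent non-edge letters swapped."""
    if len(w1) != len(w2) or w1 == w2:
        return False
    diffs = [i for i, (a, b) in enumerate(zip(w1, w2)) if a != b]
    if len(diffs) != 2 or diffs[1] != diffs[0] + 1:
        return False
    i, j = diffs
    return (
        0 < i and j < len(w1) - 1
        and w1[i] == w2[j] and w1[j] == w2[i]
    )


def find_migratable_words(lexicon: Lexicon) -> list[str]:
    """Words whose letter transposition yields another lexicon word.

    Words are grouped by letter multiset; from each anagram class of size
    >= 2 the lowest-frequency member is selected (reading errors drift
    toward the higher-frequency competitor), ties broken lexicographically.
    Classes admitting a middle-letter adjacent transposition rank first.
    """
    classes: dict[str, list[str]] = {}
    for w in lexicon:
        classes.setdefault("".join(sorted(w)), []).append(w)
    chosen: list[tuple[int, str]] = []
    for members in classes.values():
        if len(members) < 2:
            continue
        pick = min(members, key=lambda w: (lexicon.frequency(w), w))
        middle = any(
            _is_middle_transposition(pick, other)
            for other in members
            if other != pick
        )
        chosen.append((0 if middle else 1, pick))
    chosen.sort(key=lambda t: (t[0], t[1]))
    return [w for _, w in chosen]


def anagram_partner(lexicon: Lexicon, word: str) -> str | None:
    """The highest-frequency other lexicon word with the same letters,
    preferring middle-transposition neighbors."""
    key = "".join(sorted(word))
    others = [w for w in lexicon if w != word and "".join(sorted(w)) == key]
    if not others:
        return None
    return max(
        others,
        key=lambda w: (_is_middle_transposition(word, w), lexicon.frequency(w), w),
    )


def find_migratable_pairs(
    lexicon: Lexicon,
    lengths: tuple[int, ...] = (4, 5),
    shared_letters: int = 2,
    shared_at_same_position: bool = False,
) -> list[tuple[str, str, int]]:
    """Word pairs supporting a position-preserving between-word exchange.

    Returns triples ``(w1, w2, position)`` where both words have the same
    length (restricted to ``lengths``), share exactly ``shared_letters``
    letter types (optionally required to sit at identical positions), and
    swapping the letters at ``position`` yields two other lexicon words.
    """
    by_len: dict[int, list[str]] = {}
    for w in lexicon:
        if len(w) in lengths:
            by_len.setdefault(len(w), []).append(w)
    out: list[tuple[str, str, int]] = []
    for L, ws in sorted(by_len.items()):
        ws.sort()
        for w1, w2 in itertools.combinations(ws, 2):
            if shared_at_same_position:
                shared = sum(1 for a, b in zip(w1, w2) if a == b)
            else:
                shared = len(set(w1) & set(w2))
            if shared != shared_letters:
                continue
            for i in range(L):
                if w1[i] == w2[i]:
                    continue
                x1 = w1[:i] + w2[i] + w1[i + 1 :]
                x2 = w2[:i] + w1[i] + w2[i + 1 :]
                if x1 in lexicon and x2 in lexicon and x1 != w2 and x2 != w1:
                    out.append((w1, w2, i))
                    break
    return out


def find_neglect_items(lexicon: Lexicon, min_prefix: int = 2) -> list[str]:
    """Words embedding another lexicon word after a left prefix of
    >= ``min_prefix`` letters (convento -> vento), longest first."""
    out = []
    for w in lexicon:
        if any(
            w[k:] in lexicon
            for k in range(min_prefix, len(w) - 1)
            if len(w) - k >= 2
        ):
            out.append(w)
    out.sort(key=lambda w: (-len(w), w))
    return out


def vowel_neighbor_nonwords(
    lexicon: Lexicon, middle_only: bool = True
) -> list[tuple[str, str, str]]:
    """Nonwords one vowel away from lexicon words.

    For each source word, substitute one (by default middle) vowel so the
    result is *not* a word while a single vowel substitution away from the
    result *is* (the source itself, or a second neighbor like
    abote -> abate/abete).  Returns ``(nonword, source, lexicalization)``
    triples, the lexicalization being the highest-frequency word neighbor.
    """
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for w in sorted(lexicon):
        positions = [
            i for i, ch in enumerate(w)
            if ch in _VOWELS and (not middle_only or 0 < i < len(w) - 1)
        ]
        for i in positions:
            for v in _VOWELS:
                if v == w[i]:
                    continue
                cand = w[:i] + v + w[i + 1 :]
                if cand in lexicon or cand in seen:
                    continue
                neighbors = [
                    cand[:j] + u + cand[j + 1 :]
                    for j in range(len(cand))
                    if cand[j] in _VOWELS
                    for u in _VOWELS
                    if u != cand[j] and (cand[:j] + u + cand[j + 1 :]) in lexicon
                ]
                target = max(neighbors, key=lambda x: (lexicon.frequency(x), x))
                out.append((cand, w, target))
                seen.add(cand)
                break
            else:
                continue
            break
    return out


# ---------------------------------------------------------------------------
# battery assembly
# ---------------------------------------------------------------------------

#: default sublist quotas mirroring the published battery composition
DEFAULT_COMPOSITION = {
    "migratable": 20,
    "neglect": 40,
    "vowel_neighbor": 20,
    "function_abstract": 30,
    "synonym_prone": 15,
    "stress": 40,
    "pairs": 25,  # pairs of items -> 50 printed words
    "nonwords": 40,
}


@dataclass
class Battery:
    """An assembled stimulus battery plus the resources its coding needs."""

    items: list[StimulusItem]
    lexicon: Lexicon
    semantic_table: set[tuple[str, str]] = field(default_factory=set)
    #: migratable item_id -> its anagram reading
    anagram_of: dict[str, str] = field(default_factory=dict)
    #: pairs line_index -> exchange position
    exchange_position: dict[int, int] = field(default_factory=dict)
    #: nonword item_id -> (source word, lexicalization target)
    nonword_origin: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: vowel-neighbor word item_id -> its word neighbor
    vowel_neighbor_of: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.items)

    def item(self, item_id: str) -> StimulusItem:
        return next(it for it in self.items if it.item_id == item_id)


def _count_syllables(word: str) -> int:
    return sum(1 for ch in word if ch in _VOWELS)


def assemble_battery(
    lexicon: Lexicon,
    composition: dict[str, int] | None = None,
    seed: int = 0,
) -> Battery:
    """Assemble the four stimulus lists from a lexicon.

    Sublist quotas default to the published composition (125 words + 40
    stress items + 25 word pairs + 40 nonwords = 255 items).  Items never
    repeat across sublists; within-list order is randomised once per seed;
    word pairs share a line, every other list prints one item per line.
    Raises :class:`LexiconShortfallError` when the lexicon cannot fill a
    quota.
    """
    comp = dict(DEFAULT_COMPOSITION)
    comp.update(composition or {})
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    shortfalls: dict[str, tuple[int, int]] = {}

    def take(pool: list[str], need: int, key: str) -> list[str]:
        picked: list[str] = []
        for w in pool:
            if len(picked) == need:
                break
            if w not in used:
                picked.append(w)
                used.add(w)
        if len(picked) < need:
            shortfalls[key] = (need, len(picked))
        return picked

    migratable = take(find_migratable_words(lexicon), comp["migratable"], "migratable")
    neglect = take(find_neglect_items(lexicon), comp["neglect"], "neglect")

    vn_pairs: list[tuple[str, str]] = []
    for w in sorted(lexicon):
        if w in used:
            continue
        for i, ch in enumerate(w[1:-1], start=1):
            if ch not in _VOWELS:
                continue
            for v in _VOWELS:
                alt = w[:i] + v + w[i + 1 :]
                if v != ch and alt in lexicon and alt not in used:
                    a, b = sorted((w, alt), key=lambda x: (lexicon.frequency(x), x))
                    vn_pairs.append((a, b))  # keep the less frequent member
                    break
            else:
                continue
            break
    vn_words = take([a for a, _ in vn_pairs], comp["vowel_neighbor"], "vowel_neighbor")
    vn_map = dict(vn_pairs)

    tris = [w for w in sorted(lexicon) if _count_syllables(w) == 3 and len(w) == 6]
    stress_words = take(tris, comp["stress"], "stress")

    pair_triples: list[tuple[str, str, int]] = []
    for w1, w2, pos in find_migratable_pairs(lexicon):
        if len(pair_triples) == comp["pairs"]:
            break
        if w1 not in used and w2 not in used:
            pair_triples.append((w1, w2, pos))
            used.update((w1, w2))
    if len(pair_triples) < comp["pairs"]:
        shortfalls["pairs"] = (comp["pairs"], len(pair_triples))

    plain = [w for w in sorted(lexicon) if w not in used]
    rng.shuffle(plain)
    function_abstract = take(plain, comp["function_abstract"], "function_abstract")
    synonym_prone = take(
        [w for w in plain if w not in used], comp["synonym_prone"], "synonym_prone"
    )
    synonym_targets = [w for w in plain if w not in used][: len(synonym_prone)]
    semantic_table = {
        (w, t) for w, t in zip(synonym_prone, synonym_targets)
    }

    nn = [
        (nw, src, tgt)
        for (nw, src, tgt) in vowel_neighbor_nonwords(lexicon)
        if nw not in used
    ]
    if len(nn) < comp["nonwords"]:
        shortfalls["nonwords"] = (comp["nonwords"], len(nn))
    nn = nn[: comp["nonwords"]]
    used.update(nw for nw, _, _ in nn)

    if shortfalls:
        raise LexiconShortfallError(shortfalls)

    battery = Battery(items=[], lexicon=lexicon, semantic_table=semantic_table,
                      seed=seed)

    word_rows: list[tuple[str, Sublist]] = (
        [(w, Sublist.MIGRATABLE) for w in migratable]
        + [(w, Sublist.NEGLECT) for w in neglect]
        + [(w, Sublist.VOWEL_NEIGHBOR) for w in vn_words]
        + [(w, Sublist.FUNCTION_ABSTRACT) for w in function_abstract]
        + [(w, Sublist.SYNONYM_PRONE) for w in synonym_prone]
    )
    order = rng.permutation(len(word_rows))
    for line, k in enumerate(order):
        w, sub = word_rows[k]
        iid = f"W{line:03d}"
        battery.items.append(
            StimulusItem(iid, w, ListId.WORD, sub, line_index=line)
        )
        if sub == Sublist.MIGRATABLE:
            partner = anagram_partner(lexicon, w)
            if partner is not None:
                battery.anagram_of[iid] = partner
        if sub == Sublist.VOWEL_NEIGHBOR:
            battery.vowel_neighbor_of[iid] = vn_map[w]

    order = rng.permutation(len(stress_words))
    for line, k in enumerate(order):
        w = stress_words[k]
        battery.items.append(
            StimulusItem(
                f"S{line:03d}", w, ListId.STRESS, Sublist.STRESS_ITEM,
                stress_syllable=int(rng.integers(1, 3)), line_index=line,
            )
        )

    order = rng.permutation(len(pair_triples))
    for line, k in enumerate(order):
        w1, w2, pos = pair_triples[k]
        a_id, b_id = f"P{line:03d}a", f"P{line:03d}b"
        battery.items.append(
            StimulusItem(a_id, w1, ListId.PAIRS, Sublist.PAIR_MEMBER,
                         line_index=line, pair_partner=b_id)
        )
        battery.items.append(
            StimulusItem(b_id, w2, ListId.PAIRS, Sublist.PAIR_MEMBER,
                         line_index=line, pair_partner=a_id)
        )
        battery.exchange_position[line] = pos

    order = rng.permutation(len(nn))
    for line, k in enumerate(order):
        nw, src, tgt = nn[k]
        iid = f"N{line:03d}"
        battery.items.append(
            StimulusItem(iid, nw, ListId.NONWORD, Sublist.PLAIN_NONWORD,
                         line_index=line)
        )
        battery.nonword_origin[iid] = (src, tgt)

    return battery


# ---------------------------------------------------------------------------
# simulated readers and cohorts
# ---------------------------------------------------------------------------


@dataclass
class ReaderProfile:
    """Per-opportunity error probabilities of a simulated reader."""

    child_id: str = "sim"
    grade: int = 5
    theta_migration: float = 0.0     # anagram transposition on migratable words
    theta_between: float = 0.0       # exchange on word-pair lines
    theta_vowel: float = 0.0         # lexicalizing vowel substitution on nonwords
    theta_vowel_words: float = 0.0   # same on vowel-neighbor words (surface co-set)
    theta_voicing: float = 0.0       # voicing flip on words/nonwords
    theta_stress: float = 0.0        # stress shift on stress items
    theta_doubling: float = 0.0      # doubling/degemination on words/nonwords

    def __post_init__(self) -> None:
        for name in ("theta_migration", "theta_between", "theta_vowel",
                     "theta_vowel_words", "theta_voicing", "theta_stress",
                     "theta_doubling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _voicing_flip(word: str) -> str | None:
    for i in range(1, len(word)):  # prefer a non-initial site
        if word[i] in _VOICING_FLIP:
            return word[: i] + _VOICING_FLIP[word[i]] + word[i + 1 :]
    if word and word[0] in _VOICING_FLIP:
        return _VOICING_FLIP[word[0]] + word[1:]
    return None


def _doubling_change(word: str) -> str | None:
    for i in range(len(word) - 1):
        if word[i] == word[i + 1]:
            return word[:i] + word[i + 1 :]  # degeminate
    for i in range(1, len(word) - 1):
        if word[i] in _CONSONANTS:
            return word[: i + 1] + word[i] + word[i + 1 :]  # double a middle consonant
    return None


def simulate_reader(
    profile: ReaderProfile, battery: Battery, seed: int = 0
) -> list[ResponseRecord]:
    """Simulate one reading of the battery under a reader profile.

    Each item (or pair line) receives at most one signature error, drawn per
    opportunity type present on that item; otherwise the correct reading is
    emitted.  Stress items are always read segmentally correctly, with the
    stress position erring at ``theta_stress``.
    """
    rng = np.random.default_rng(seed)
    out: list[ResponseRecord] = []
    pair_lines_done: dict[int, bool] = {}
    for it in battery.items:
        text = it.text
        stress = it.stress_syllable
        if it.list_id == ListId.STRESS:
            if rng.random() < profile.theta_stress:
                stress = 2 if it.stress_syllable == 1 else 1
        elif it.list_id == ListId.PAIRS:
            line = it.line_index
            if line not in pair_lines_done:
                pair_lines_done[line] = rng.random() < profile.theta_between
            if pair_lines_done[line]:
                partner = battery.item(it.pair_partner)
                pos = battery.exchange_position[line]
                if pos < min(len(text), len(partner.text)):
                    text = text[:pos] + partner.text[pos] + text[pos + 1 :]
        else:
            applied = False
            if it.item_id in battery.anagram_of and rng.random() < profile.theta_migration:
                text = battery.anagram_of[it.item_id]
                applied = True
            if not applied and it.list_id == ListId.NONWORD:
                if rng.random() < profile.theta_vowel:
                    text = battery.nonword_origin[it.item_id][1]
                    applied = True
            if not applied and it.item_id in battery.vowel_neighbor_of:
                if rng.random() < profile.theta_vowel_words:
                    text = battery.vowel_neighbor_of[it.item_id]
                    applied = True
            if not applied and rng.random() < profile.theta_voicing:
                flipped = _voicing_flip(text)
                if flipped is not None:
                    text = flipped
                    applied = True
            if not applied and rng.random() < profile.theta_doubling:
                changed = _doubling_change(text)
                if changed is not None:
                    text = changed
        out.append(
            ResponseRecord(profile.child_id, profile.grade, it.item_id, text,
                           response_stress=stress)
        )
    return out


def _cell_draws(M: float, SD: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Error-count draws moment-matched to (M, SD).

    Negative binomial when overdispersed (SD^2 > M), Poisson otherwise;
    degenerate cells (M = 0, SD = 0) draw constant zeros.
    """
    var = SD * SD
    if M <= 0:
        return np.zeros(size, dtype=int)
    if var > M:
        p = M / var
        r = M * p / (1 - p)
        return rng.negative_binomial(r, p, size=size)
    return rng.poisson(M, size=size)


def simulate_cohort(
    norms: NormTable,
    n_per_grade: int,
    seed: int = 0,
    grades: list[int] | None = None,
) -> list[ClusterScore]:
    """Draw a cohort of cluster scores from a normative table.

    Each non-Total cell of each grade receives independent moment-matched
    count draws; the summary Total indexes are recomputed as sums of the
    cluster draws within each list group.  The two normative views
    (stress-list Surface, pairs migrations) are drawn from their own cells.
    """
    rng = np.random.default_rng(seed)
    out: list[ClusterScore] = []
    for grade in grades or norms.grades:
        cells = norms.grade_cells(grade)
        draws = {
            key: _cell_draws(cell.M, cell.SD, n_per_grade, rng)
            for key, cell in sorted(cells.items())
            if key[0] != "Total"
        }
        for i in range(n_per_grade):
            cs = ClusterScore(child_id=f"sim-g{grade}-{i:05d}", grade=grade)
            for (label, lg), arr in draws.items():
                v = Fraction(int(arr[i]))
                if label == "SurfaceStressList":
                    cs.surface_stress_list = v
                elif label == "PairsMigrations":
                    cs.pairs_migrations = v
                else:
                    cs.scores[(label, lg)] = v
            out.append(cs)
    return out
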