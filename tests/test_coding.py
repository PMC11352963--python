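"""Alignment, error detectors and response classification."""

import heapq
import itertools
from fractions import Fraction

import numpy as np
import pytest

import lettura as L
from lettura.coding import (
    CodingContext,
    CodingResources,
    EditOp,
    ErrorType,
    ListId,
    ResponseRecord,
    Source,
    StimulusItem,
    Sublist,
    Unit,
    detect_between_word_migration,
    detect_doubling,
    detect_morphological,
    detect_neglect,
    detect_semantic,
    detect_stress_error,
    edit_script,
    is_anagram_migration,
)
from lettura.orthography import PositionZone, parse_graphemes


def ids(word):
    return tuple(g.identity for g in parse_graphemes(word))


def replay(target, script):
    """Apply an edit script to a target identity tuple (oracle for scripts)."""
    cur = list(ids(target)) if isinstance(target, str) else list(target)
    for op in script:
        if op.op == "substitute":
            cur[op.index] = op.new
        elif op.op == "delete":
            del cur[op.index]
        elif op.op == "insert":
            cur.insert(op.index, op.new)
        else:  # move
            g = cur.pop(op.src_index)
            cur.insert(op.index, g)
    return tuple(cur)


# ---------------------------------------------------------------------------
# edit script
# ---------------------------------------------------------------------------


def test_edit_script_identity():
    assert edit_script(parse_graphemes("pane"), parse_graphemes("pane")) == []


def test_edit_script_vowel_addition():
    script = edit_script(parse_graphemes("carta"), parse_graphemes("carota"))
    assert len(script) == 1
    assert script[0].op == "insert" and script[0].new == "o"


def test_edit_script_adjacent_move():
    script = edit_script(parse_graphemes("lardo"), parse_graphemes("ladro"))
    assert len(script) == 1
    assert script[0].op == "move"


def test_edit_script_replays_to_response():
    for t, r in [("lardo", "ladro"), ("vondesta", "voldestra"),
                 ("carta", "carota"), ("convento", "vento")]:
        script = edit_script(parse_graphemes(t), parse_graphemes(r))
        assert replay(t, script) == ids(r)


def _levenshtein(a, b):
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[m][n]


def brute_force_cost(start, goal):
    """Dijkstra over all unit-cost edits (ops at any position, incl. moves).

    Independent of the production search: ops are tried at every position,
    not just the leftmost mismatch, with the plain Levenshtein distance as
    an upper bound."""
    bound = _levenshtein(start, goal)
    letters = sorted(set(goal))
    heap = [(0, start)]
    best = {start: 0}
    while heap:
        cost, cur = heapq.heappop(heap)
        if cur == goal:
            return cost
        if cost >= bound or cost > best.get(cur, cost):
            continue
        succ = set()
        for i in range(len(cur)):
            succ.add(cur[:i] + cur[i + 1 :])  # delete
            for x in letters:
                if x != cur[i]:
                    succ.add(cur[:i] + (x,) + cur[i + 1 :])  # substitute
        for i in range(len(cur) + 1):
            for x in letters:
                succ.add(cur[:i] + (x,) + cur[i:])  # insert
        for i in range(len(cur)):  # move i -> j
            rest = cur[:i] + cur[i + 1 :]
            for j in range(len(rest) + 1):
                succ.add(rest[:j] + (cur[i],) + rest[j:])
        for nxt in succ:
            if cost + 1 < best.get(nxt, bound + 1):
                best[nxt] = cost + 1
                heapq.heappush(heap, (cost + 1, nxt))
    return bound


def test_edit_cost_matches_oracle_exhaustive_binary_alphabet():
    """All target/response pairs of length <= 4 over a two-letter alphabet."""
    words = [tuple(p) for n in range(1, 5) for p in itertools.product("ab", repeat=n)]
    fake = {"a": parse_graphemes("a")[0], "b": parse_graphemes("b")[0]}
    for t in words:
        for r in words:
            gt = [fake[x] for x in t]
            gr = [fake[x] for x in r]
            script = edit_script(gt, gr)
            assert replay(t, script) == r
            assert len(script) == brute_force_cost(t, r)


def test_edit_cost_matches_oracle_sampled_five_letters():
    """Sampled nearby pairs of length <= 6 over a five-letter alphabet."""
    rng = np.random.default_rng(7)
    alphabet = "abdel"
    fake = {x: parse_graphemes(x)[0] for x in alphabet}
    for _ in range(120):
        n = int(rng.integers(2, 7))
        t = tuple(rng.choice(list(alphabet), n))
        r = list(t)
        for _ in range(int(rng.integers(1, 4))):  # perturb up to 3 times
            kind = rng.integers(4)
            if kind == 0 and r:
                i = int(rng.integers(len(r)))
                r[i] = rng.choice(list(alphabet))
            elif kind == 1 and r:
                del r[int(rng.integers(len(r)))]
            elif kind == 2 and len(r) < 7:
                r.insert(int(rng.integers(len(r) + 1)), rng.choice(list(alphabet)))
            elif r:
                i, j = rng.integers(len(r)), rng.integers(len(r))
                g = r.pop(int(i))
                r.insert(int(j), g)
        r = tuple(r)
        script = edit_script([fake[x] for x in t], [fake[x] for x in r])
        assert replay(t, script) == r
        assert len(script) == brute_force_cost(t, r)


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t, r, expected",
    [
        ("corpo", "copro", True),
        ("pane", "pane", False),
        ("lardo", "largo", False),  # multiset differs (d vs g)
    ],
)
def test_anagram_migration(t, r, expected):
    got, moved = is_anagram_migration(parse_graphemes(t), parse_graphemes(r))
    assert got is expected
    if expected:
        assert moved  # displaced indices reported
    # brute-force multiset comparison agrees
    assert (sorted(ids(t)) == sorted(ids(r)) and ids(t) != ids(r)) is expected


def test_neglect_omission_lexicalized():
    lex = {"dente", "vento", "incidente", "convento"}
    for carrier, part in [("incidente", "dente"), ("convento", "vento")]:
        code = detect_neglect(parse_graphemes(carrier), parse_graphemes(part), lex)
        assert code.etype == ErrorType.NEGLECT_LEFT
        assert code.position == PositionZone.EXTERIOR_LEFT
        assert code.lexicalized


def test_neglect_none_on_identity_and_non_prefix_errors():
    assert detect_neglect(parse_graphemes("convento"), parse_graphemes("convento")) is None
    # difference not confined to a left prefix
    assert detect_neglect(parse_graphemes("convento"), parse_graphemes("convenno")) is None


def test_between_word_migration_pairs():
    codes = detect_between_word_migration(["viso", "vano"], ["vino", "vaso"])
    assert len(codes) == 2
    assert all(c.etype == ErrorType.BETWEEN_WORD_MIGRATION for c in codes)
    assert all(c.source == Source.HORIZONTAL for c in codes)
    assert all("@2" in c.detail for c in codes)  # third letter position

    codes = detect_between_word_migration(["cena", "pera"], ["pena", "cera"])
    assert len(codes) == 2
    assert all(c.position == PositionZone.EXTERIOR_LEFT for c in codes)

    assert detect_between_word_migration(["viso", "vano"], ["viso", "vano"]) == []


def test_stress_error_detection():
    item = StimulusItem("s1", "sabato", ListId.STRESS, Sublist.STRESS_ITEM,
                        stress_syllable=1)
    code = detect_stress_error(item, 2, segmental_ok=True)
    assert code.etype == ErrorType.STRESS_SHIFT
    assert code.unit == Unit.NOT_APPLICABLE
    assert detect_stress_error(item, 1, segmental_ok=True) is None
    assert detect_stress_error(item, 2, segmental_ok=False) is None
    nonword = StimulusItem("n1", "vondesta", ListId.NONWORD, Sublist.PLAIN_NONWORD)
    assert detect_stress_error(nonword, 2, segmental_ok=True) is None


@pytest.mark.parametrize(
    "t, r, etype",
    [
        ("palla", "pala", ErrorType.DOUBLING_OMISSION),
        ("pala", "palla", ErrorType.DOUBLING),
        ("pane", "pane", None),
        ("pane", "pano", None),  # substitution defers to general coding
    ],
)
def test_doubling_detection(t, r, etype):
    code = detect_doubling(parse_graphemes(t), parse_graphemes(r))
    if etype is None:
        assert code is None
    else:
        assert code.etype == etype


def test_semantic_detection():
    table = {("circa", "quasi"), ("selva", "bosco"), ("sabbia", "spiaggia")}
    for t, r in table:
        code = detect_semantic(t, r, table)
        assert code is not None and code.etype == ErrorType.SEMANTIC
        assert code.unit == Unit.WHOLE_WORD
    assert detect_semantic("circa", "quasi", None) is None
    assert detect_semantic("abate", "abete", table) is None  # not in table


def test_morphological_detection():
    code = detect_morphological(parse_graphemes("premettere"), parse_graphemes("mettere"))
    assert code is not None and code.etype == ErrorType.MORPHOLOGICAL
    assert code.unit == Unit.AFFIX
    assert detect_morphological(parse_graphemes("mettere"), parse_graphemes("mettere")) is None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify(target, response, list_id=ListId.WORD, sublist=Sublist.FUNCTION_ABSTRACT,
             context=None, resources=None, stress=None, response_stress=None):
    item = StimulusItem("i1", target, list_id, sublist, stress_syllable=stress)
    rec = ResponseRecord("c1", 3, "i1", response, response_stress=response_stress)
    return L.classify_response(item, rec, context, resources)


def test_classify_correct_response_is_empty():
    assert classify("pane", "pane").is_correct


def test_classify_within_word_migration():
    cr = classify("lardo", "ladro", sublist=Sublist.MIGRATABLE)
    (group,) = cr.groups
    (code,) = group
    assert code.etype == ErrorType.WITHIN_WORD_MIGRATION
    assert code.weight == 1


def test_classify_anagram_beats_morphology():
    cr = classify("corpo", "copro")
    assert all(c.etype == ErrorType.WITHIN_WORD_MIGRATION for c in cr.all_codes())


def test_classify_or_coding_addition_vs_vertical_migration():
    """An addition that matches the line below is a two-way "or" group."""
    cr = classify("prati", "pirati", sublist=Sublist.MIGRATABLE,
                  context=CodingContext(below_text="circo"))
    (group,) = cr.groups
    assert len(group) == 2
    etypes = {c.etype for c in group}
    assert etypes == {ErrorType.ADDITION, ErrorType.BETWEEN_WORD_MIGRATION}
    assert all(c.weight == Fraction(1, 2) for c in group)
    mig = next(c for c in group if c.etype == ErrorType.BETWEEN_WORD_MIGRATION)
    assert mig.source == Source.VERTICAL
    add = next(c for c in group if c.etype == ErrorType.ADDITION)
    assert add.unit == Unit.VOWEL


def test_classify_and_coding_two_errors():
    cr = classify("vondesta", "voldestra", list_id=ListId.NONWORD,
                  sublist=Sublist.PLAIN_NONWORD)
    assert len(cr.groups) == 2
    codes = sorted(cr.all_codes(), key=lambda c: c.etype.value)
    assert codes[0].etype == ErrorType.ADDITION and codes[0].unit == Unit.CONSONANT
    assert codes[1].etype == ErrorType.SUBSTITUTION and codes[1].unit == Unit.CONSONANT
    assert all(c.weight == 1 for c in codes)


def test_classify_lexicalized_vowel_substitution():
    res = CodingResources(lexicon={"abate", "abete"})
    cr = classify("abate", "abete", sublist=Sublist.VOWEL_NEIGHBOR, resources=res)
    (group,) = cr.groups
    (code,) = group
    assert code.etype == ErrorType.SUBSTITUTION
    assert code.unit == Unit.VOWEL
    assert code.position == PositionZone.MIDDLE
    assert code.lexicalized


def test_classify_nonword_lexicalization():
    res = CodingResources(lexicon={"brodo"})
    cr = classify("bredo", "brodo", list_id=ListId.NONWORD,
                  sublist=Sublist.PLAIN_NONWORD, resources=res)
    (code,) = next(iter(cr.groups))
    assert code.unit == Unit.VOWEL and code.lexicalized


def test_classify_stress_shift():
    cr = classify("sabato", "sabato", list_id=ListId.STRESS,
                  sublist=Sublist.STRESS_ITEM, stress=1, response_stress=2)
    (group,) = cr.groups
    assert group[0].etype == ErrorType.STRESS_SHIFT


def test_classify_voicing_and_nasality_units():
    cr = classify("pane", "bane")
    (code,) = next(iter(cr.groups))
    assert code.unit == Unit.VOICING_FEATURE
    cr = classify("pane", "pade")  # homorganic denasalization n -> d
    (code,) = next(iter(cr.groups))
    assert code.unit == Unit.NASALITY_FEATURE


def test_classify_multi_letter_rule_unit():
    cr = classify("chiesa", "tiesa")
    (code,) = next(iter(cr.groups))
    assert code.unit == Unit.MULTI_LETTER_RULE


def test_classify_no_response():
    cr = classify("pane", "")
    (code,) = next(iter(cr.groups))
    assert code.etype == ErrorType.NO_RESPONSE
    assert code.unit == Unit.WHOLE_WORD and code.weight == 1


def test_self_correction_flag_carried():
    item = StimulusItem("i1", "lardo", ListId.WORD, Sublist.MIGRATABLE)
    rec = ResponseRecord("c1", 3, "i1", "ladro", self_corrected=True)
    cr = L.classify_response(item, rec)
    plain = L.classify_response(item, ResponseRecord("c1", 3, "i1", "ladro"))
    assert cr.self_corrected and not plain.self_corrected
    assert cr.groups == plain.groups


def test_weight_conservation_over_simulated_battery(battery, resources):
    """Every "or" group over a noisy full battery sums to exactly 1."""
    profile = L.ReaderProfile(
        child_id="noisy", grade=4, theta_migration=0.4, theta_between=0.4,
        theta_vowel=0.4, theta_voicing=0.4, theta_stress=0.4, theta_doubling=0.4,
    )
    records = L.simulate_reader(profile, battery, seed=11)
    coded = L.code_battery(battery.items, records, resources)
    n_groups = 0
    for cr in coded:
        for group in cr.groups:
            n_groups += 1
            assert sum(c.weight for c in group) == Fraction(1)
            assert len({c.weight for c in group}) == 1
    assert n_groups > 50  # the noisy reader actually erred


def test_correct_battery_codes_empty(battery, resources):
    quiet = L.ReaderProfile(child_id="quiet", grade=4)
    records = L.simulate_reader(quiet, battery, seed=3)
    coded = L.code_battery(battery.items, records, resources)
    assert all(cr.is_correct for cr in coded)


def test_code_battery_requires_pair_partner_response(battery, resources):
    pair_item = next(it for it in battery.items if it.list_id == ListId.PAIRS)
    rec = ResponseRecord("c9", 4, pair_item.item_id, pair_item.text)
    with pytest.raises(ValueError, match="partner"):
        L.code_battery(battery.items, [rec], resources)
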