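"""Synthetic lexicon, stimulus searches, battery assembly and simulation."""

import itertools
from collections import Counter

import numpy as np
import pytest

import lettura as L
from lettura.coding import ListId, Sublist
from lettura.synthesis import (
    DEFAULT_COMPOSITION,
    Battery,
    Lexicon,
    LexiconShortfallError,
    anagram_partner,
    find_migratable_pairs,
    find_migratable_words,
    find_neglect_items,
    synth_lexicon,
    vowel_neighbor_nonwords,
)


# ---------------------------------------------------------------------------
# synthetic lexicon
# ---------------------------------------------------------------------------


def test_synth_lexicon_deterministic():
    a, b = synth_lexicon(5, 500), synth_lexicon(5, 500)
    assert a.entries == b.entries
    assert synth_lexicon(6, 500).entries != a.entries


def test_synth_lexicon_alphabet_and_size(lexicon):
    assert len(lexicon) == 1200
    assert lexicon.alphabet <= set("abcdefghiklmnopqrstuvz")
    assert all(f > 0 for f in lexicon.entries.values())


def test_synth_lexicon_anagram_quota():
    """Exhaustive anagram scan confirms the construction guarantee."""
    lex = synth_lexicon(5, 500)
    classes = Counter("".join(sorted(w)) for w in lex)
    assert sum(1 for c in classes.values() if c >= 2) >= 10


def test_synth_lexicon_rejects_tiny_size():
    with pytest.raises(ValueError):
        synth_lexicon(1, 50)


# ---------------------------------------------------------------------------
# stimulus searches
# ---------------------------------------------------------------------------


def test_migratable_words_pick_less_frequent():
    lex = Lexicon({"corpo": 5.0, "copro": 1.0, "pane": 9.0})
    assert find_migratable_words(lex) == ["copro"]
    assert anagram_partner(lex, "copro") == "corpo"


def test_migratable_words_empty_without_anagrams():
    assert find_migratable_words(Lexicon({"pane": 1.0, "vino": 1.0})) == []


def test_migratable_words_one_per_class():
    lex = Lexicon({"post": 3.0, "pots": 2.0, "tops": 1.0})
    picked = find_migratable_words(lex)
    assert picked == ["tops"]  # lowest frequency of the three-member class


def test_migratable_pairs_reference_quad():
    lex = Lexicon({w: 1.0 for w in ("cena", "pera", "pena", "cera")})
    triples = find_migratable_pairs(lex)
    assert ("cena", "pera", 0) in triples


def test_migratable_pairs_oracle_equivalence(lexicon):
    """Output matches an O(n^2 * L) brute-force search on a 50-word slice."""
    words = [w for w in sorted(lexicon) if len(w) in (4, 5)][:50]
    lex = Lexicon({w: lexicon.frequency(w) for w in words})
    got = set(find_migratable_pairs(lex))
    brute = set()
    for w1, w2 in itertools.combinations(sorted(words), 2):
        if len(w1) != len(w2) or len(set(w1) & set(w2)) != 2:
            continue
        for i in range(len(w1)):
            if w1[i] == w2[i]:
                continue
            x1 = w1[:i] + w2[i] + w1[i + 1 :]
            x2 = w2[:i] + w1[i] + w2[i + 1 :]
            if x1 in lex and x2 in lex and x1 != w2 and x2 != w1:
                brute.add((w1, w2, i))
                break
    assert got == brute


def test_neglect_items_reference_and_oracle(lexicon):
    lex = Lexicon({"convento": 1.0, "vento": 2.0, "incidente": 1.0,
                   "dente": 3.0, "pane": 1.0})
    assert find_neglect_items(lex) == ["incidente", "convento"]  # longest first
    assert find_neglect_items(Lexicon({"pane": 1.0, "vino": 1.0})) == []
    # brute force on the synthetic lexicon
    got = set(find_neglect_items(lexicon))
    brute = {
        w for w in lexicon
        if any(w[k:] in lexicon for k in range(2, len(w) - 1))
    }
    assert got == brute


def test_vowel_neighbor_nonwords_reference():
    lex = Lexicon({"abate": 1.0, "abete": 5.0, "brodo": 3.0})
    triples = vowel_neighbor_nonwords(lex)
    by_source = {src: (nw, tgt) for nw, src, tgt in triples}
    nw, tgt = by_source["abate"]
    assert nw not in lex and len(nw) == 5
    assert tgt in {"abate", "abete"}
    for nw, src, tgt in triples:
        assert nw not in lex and tgt in lex
        # nonword differs from its source by exactly one middle vowel
        diffs = [i for i, (a, b) in enumerate(zip(nw, src)) if a != b]
        assert len(diffs) == 1 and 0 < diffs[0] < len(src) - 1
        assert src[diffs[0]] in "aeiou" and nw[diffs[0]] in "aeiou"


# ---------------------------------------------------------------------------
# battery assembly
# ---------------------------------------------------------------------------


def test_battery_composition(battery):
    assert len(battery.items) == 255
    counts = Counter(it.sublist for it in battery.items)
    assert counts[Sublist.MIGRATABLE] == 20
    assert counts[Sublist.NEGLECT] == 40
    assert counts[Sublist.VOWEL_NEIGHBOR] == 20
    assert counts[Sublist.FUNCTION_ABSTRACT] == 30
    assert counts[Sublist.SYNONYM_PRONE] == 15
    assert counts[Sublist.STRESS_ITEM] == 40
    assert counts[Sublist.PAIR_MEMBER] == 50
    assert counts[Sublist.PLAIN_NONWORD] == 40


def test_battery_pairs_layout(battery):
    pairs = [it for it in battery.items if it.list_id == ListId.PAIRS]
    lines = Counter(it.line_index for it in pairs)
    assert len(lines) == 25 and set(lines.values()) == {2}
    by_id = {it.item_id: it for it in pairs}
    for it in pairs:
        partner = by_id[it.pair_partner]
        assert partner.pair_partner == it.item_id
        assert partner.line_index == it.line_index
        assert len(partner.text) == len(it.text)


def test_battery_no_duplicate_items(battery):
    texts = [it.text for it in battery.items]
    assert len(texts) == len(set(texts))
    ids = [it.item_id for it in battery.items]
    assert len(ids) == len(set(ids))


def test_battery_stress_items_marked(battery):
    for it in battery.items:
        if it.list_id == ListId.STRESS:
            assert it.stress_syllable in (1, 2)
        else:
            assert it.stress_syllable is None


def test_battery_seed_reproducible(lexicon):
    a = L.assemble_battery(lexicon, seed=9)
    b = L.assemble_battery(lexicon, seed=9)
    assert [(i.item_id, i.text, i.line_index) for i in a.items] == [
        (i.item_id, i.text, i.line_index) for i in b.items
    ]


def test_battery_shortfall_error():
    lex = synth_lexicon(2, 120, anagram_pairs=2, exchange_quads=2,
                        neglect_carriers=2, vowel_pairs=2, trisyllabic=5)
    with pytest.raises(LexiconShortfallError) as exc:
        L.assemble_battery(lex)
    assert exc.value.shortfalls  # names the lacking sublists


# ---------------------------------------------------------------------------
# simulated readers and cohorts
# ---------------------------------------------------------------------------


def test_reader_all_theta_zero_reads_correctly(battery):
    recs = L.simulate_reader(L.ReaderProfile(child_id="q", grade=3), battery, seed=1)
    by_id = {it.item_id: it for it in battery.items}
    assert len(recs) == 255
    for r in recs:
        assert r.response_text == by_id[r.item_id].text
        assert r.response_stress == by_id[r.item_id].stress_syllable


def test_reader_pure_lpd_theta_one(battery):
    prof = L.ReaderProfile(child_id="lpd", grade=3, theta_migration=1.0)
    recs = L.simulate_reader(prof, battery, seed=1)
    by_id = {it.item_id: it for it in battery.items}
    for r in recs:
        it = by_id[r.item_id]
        if it.item_id in battery.anagram_of:
            assert r.response_text == battery.anagram_of[it.item_id]
            assert sorted(r.response_text) == sorted(it.text)
        else:
            assert r.response_text == it.text


def test_reader_pure_surface_theta_one(battery):
    prof = L.ReaderProfile(child_id="surf", grade=3, theta_stress=1.0)
    recs = L.simulate_reader(prof, battery, seed=1)
    by_id = {it.item_id: it for it in battery.items}
    for r in recs:
        it = by_id[r.item_id]
        assert r.response_text == it.text  # segmentally correct everywhere
        if it.list_id == ListId.STRESS:
            assert r.response_stress != it.stress_syllable
        else:
            assert r.response_stress == it.stress_syllable


def test_reader_profile_validates_theta():
    with pytest.raises(ValueError):
        L.ReaderProfile(theta_migration=1.5)


def test_simulate_cohort_reproducible_and_calibrated(embedded_norms):
    a = L.simulate_cohort(embedded_norms, 100, seed=3, grades=[2])
    b = L.simulate_cohort(embedded_norms, 100, seed=3, grades=[2])
    assert [(c.child_id, sorted(c.scores.items())) for c in a] == [
        (c.child_id, sorted(c.scores.items())) for c in b
    ]
    big = L.simulate_cohort(embedded_norms, 5000, seed=4, grades=[2])
    vals = np.array([float(c.get("Attentional", "words")) for c in big])
    cell = embedded_norms.get(2, "Attentional", "words")
    assert abs(vals.mean() - cell.M) < 2 * cell.SD / np.sqrt(5000)
    # overdispersion carried through (SD^2 > M for this cell)
    assert vals.var() > vals.mean() * 1.2


def test_simulate_cohort_poisson_branch(embedded_norms):
    # grade-8 nonwords Attentional has SD^2 = 0.36 <= M = 0.5
    cohort = L.simulate_cohort(embedded_norms, 4000, seed=5, grades=[8])
    vals = np.array([float(c.get("Attentional", "nonwords")) for c in cohort])
    assert abs(vals.mean() - 0.5) < 2 * 0.6 / np.sqrt(4000) + 0.05
    assert vals.var() == pytest.approx(vals.mean(), rel=0.2)  # Poisson-like
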