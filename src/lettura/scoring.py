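"""Accumulate error codes into dyslexia-type cluster scores.

Each classified error feeds one or more *clusters*, each cluster named after
the dyslexia type whose signature it collects:

===============  ===========================================================
Attentional      between-word migrations
LetterPosition   within-word migrations (anagrams)
Surface          stress-shift errors
MultiLetter      errors on multi-letter conversion-rule units
Vowel            vowel substitutions/additions/omissions, and (by default)
                 every other error involving a vowel: migrations within and
                 between words, vowel doubling
Consonant        consonant substitution, omission, addition, nasality errors
Voicing          voicing-feature substitutions
Doubling         doubling and doubling-omission errors
Deep             semantic and morphological whole-word errors
Neglect          left-side neglect patterns
===============  ===========================================================

Scores are exact fractions (sums of "or"-group weights 1, 1/2, 1/3) and are
aggregated per list group — words (word + stress lists), pairs, nonwords —
plus the four summary indexes.  Two normative views are materialised on top:
Surface errors restricted to the stress list, and between-word migrations in
the word-pairs list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coding import CodedResponse, ErrorCode, ErrorType, ListId, StimulusItem, Unit

__all__ = [
    "CLUSTERS",
    "LIST_GROUPS",
    "ClusterScore",
    "code_to_clusters",
    "score_child",
    "cohort_table",
]

CLUSTERS = (
    "Attentional",
    "LetterPosition",
    "Surface",
    "MultiLetter",
    "Vowel",
    "Consonant",
    "Voicing",
    "Doubling",
    "Deep",
    "Neglect",
)

LIST_GROUPS = ("words", "pairs", "nonwords")

_LIST_GROUP_OF = {
    ListId.WORD: "words",
    ListId.STRESS: "words",
    ListId.PAIRS: "pairs",
    ListId.NONWORD: "nonwords",
}


def code_to_clusters(code: ErrorCode, vowel_migrations_feed_vowel: bool = True) -> set[str]:
    """Map one error code to the cluster(s) it scores in.

    A migration or doubling of a vowel feeds the Vowel cluster in addition to
    its own cluster when ``vowel_migrations_feed_vowel`` (the default), since
    the Vowel cluster collects *all* errors in which vowels are involved.
    No-response codes enter no cluster (they count only toward raw totals).
    """
    out: set[str] = set()
    et, unit = code.etype, code.unit
    if et == ErrorType.NO_RESPONSE:
        return out
    if et == ErrorType.BETWEEN_WORD_MIGRATION:
        out.add("Attentional")
    elif et == ErrorType.WITHIN_WORD_MIGRATION:
        out.add("LetterPosition")
    elif et == ErrorType.STRESS_SHIFT:
        out.add("Surface")
    elif et in (ErrorType.DOUBLING, ErrorType.DOUBLING_OMISSION):
        out.add("Doubling")
    elif et in (ErrorType.SEMANTIC, ErrorType.MORPHOLOGICAL):
        out.add("Deep")
    elif et == ErrorType.NEGLECT_LEFT:
        out.add("Neglect")
    elif et in (ErrorType.SUBSTITUTION, ErrorType.ADDITION, ErrorType.OMISSION):
        if unit == Unit.VOICING_FEATURE:
            out.add("Voicing")
        elif unit == Unit.NASALITY_FEATURE:
            out.add("Consonant")
        elif unit == Unit.MULTI_LETTER_RULE:
            out.add("MultiLetter")
        elif unit == Unit.VOWEL:
            out.add("Vowel")
        elif unit == Unit.CONSONANT:
            out.add("Consonant")
    if (
        vowel_migrations_feed_vowel
        and unit == Unit.VOWEL
        and et
        in (
            ErrorType.WITHIN_WORD_MIGRATION,
            ErrorType.BETWEEN_WORD_MIGRATION,
            ErrorType.DOUBLING,
            ErrorType.DOUBLING_OMISSION,
        )
    ):
        out.add("Vowel")
    return out


@dataclass
class ClusterScore:
    """Per-child fractional error totals per cluster and list group."""

    child_id: str
    grade: int
    scores: dict[tuple[str, str], Fraction] = field(default_factory=dict)
    #: Surface errors accrued on stress-list items only (normative view)
    surface_stress_list: Fraction = Fraction(0)
    #: between-word migrations accrued in the word-pairs list (normative view)
    pairs_migrations: Fraction = Fraction(0)

    def get(self, cluster: str, list_group: str) -> Fraction:
        return self.scores.get((cluster, list_group), Fraction(0))

    def list_total(self, list_group: str) -> Fraction:
        return sum(
            (v for (c, lg), v in self.scores.items() if lg == list_group),
            Fraction(0),
        )

    @property
    def words_total(self) -> Fraction:
        return self.list_total("words")

    @property
    def pairs_total(self) -> Fraction:
        return self.list_total("pairs")

    @property
    def nonwords_total(self) -> Fraction:
        return self.list_total("nonwords")

    @property
    def overall(self) -> Fraction:
        return self.words_total + self.pairs_total + self.nonwords_total

    def norm_value(self, label: str, list_group: str) -> Fraction:
        """Value compared against a normative cell (handles the two views
        and the Total index)."""
        if label == "Total":
            return self.list_total(list_group)
        if label == "SurfaceStressList":
            return self.surface_stress_list
        if label == "PairsMigrations":
            return self.pairs_migrations
        return self.get(label, list_group)


def score_child(
    coded: Iterable[CodedResponse],
    items: Sequence[StimulusItem] | Mapping[str, StimulusItem],
    child_id: str | None = None,
    grade: int = 0,
    vowel_migrations_feed_vowel: bool = True,
) -> ClusterScore:
    """Sum a child's code weights into cluster x list-group cells."""
    if not isinstance(items, Mapping):
        items = {it.item_id: it for it in items}
    coded = list(coded)
    if child_id is None:
        ids = {c.child_id for c in coded}
        if len(ids) != 1:
            raise ValueError(f"expected one child_id, got {sorted(ids)}")
        child_id = ids.pop()
    score = ClusterScore(child_id=child_id, grade=grade)
    for cr in coded:
        item = items.get(cr.item_id)
        if item is None:
            raise KeyError(f"unresolved item_id {cr.item_id!r}")
        lg = _LIST_GROUP_OF[item.list_id]
        for code in cr.all_codes():
            for cluster in code_to_clusters(code, vowel_migrations_feed_vowel):
                key = (cluster, lg)
                score.scores[key] = score.scores.get(key, Fraction(0)) + code.weight
                if cluster == "Surface" and item.list_id == ListId.STRESS:
                    score.surface_stress_list += code.weight
                if cluster == "Attentional" and item.list_id == ListId.PAIRS:
                    score.pairs_migrations += code.weight
    return score


def cohort_table(children: Sequence[ClusterScore]) -> pd.DataFrame:
    """Long-format score table: one row per child x cluster x list group.

    Includes the four summary indexes as pseudo-clusters (``Total`` per list
    group plus ``Overall``) and the two normative views, so downstream norming
    can treat every normable quantity uniformly.
    """
    if not children:
        raise ValueError("empty cohort")
    seen: set[str] = set()
    rows = []
    for cs in children:
        if cs.child_id in seen:
            raise ValueError(f"duplicated child_id {cs.child_id!r}")
        seen.add(cs.child_id)
        for cluster in CLUSTERS:
            for lg in LIST_GROUPS:
                rows.append((cs.child_id, cs.grade, cluster, lg, float(cs.get(cluster, lg))))
        for lg in LIST_GROUPS:
            rows.append((cs.child_id, cs.grade, "Total", lg, float(cs.list_total(lg))))
        rows.append((cs.child_id, cs.grade, "Overall", "all", float(cs.overall)))
        rows.append((cs.child_id, cs.grade, "SurfaceStressList", "words",
                     float(cs.surface_stress_list)))
        rows.append((cs.child_id, cs.grade, "PairsMigrations", "pairs",
                     float(cs.pairs_migrations)))
    return pd.DataFrame(rows, columns=["child_id", "grade", "cluster", "list_group", "score"])
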