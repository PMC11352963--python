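"""Single-case diagnosis against normative tables, and instrument agreement.

A child's cluster scores are compared cell by cell with the grade's norms:
a cell is *flagged* when the (possibly fractional) score reaches the integer
abnormality cutoff (score >= threshold; the cutoff is the first abnormal
count, so comparison is inclusive by default and configurable).  A profile
with exactly one flagged cluster — counting a cluster once across list
groups — is a *pure* dyslexia of that type; more than one is *mixed*.

On top of the flags, selective sublexical-route patterns are labelled: a
consonant deficit confined to nonwords with intact vowels points at a
consonant grapheme–phoneme conversion deficit (and symmetrically for
vowels), while consonant errors in both words and nonwords are the candidate
signature of a letter-identity deficit upstream of both routes.

Agreement between two dichotomous screenings over the same children is
summarised as a 2×2 table with a Pearson chi-square (no continuity
correction, 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .norming import NormTable
from .scoring import ClusterScore

__all__ = [
    "DiagnosticProfile",
    "AgreementTable",
    "flag_profile",
    "selective_sublexical",
    "agreement",
    "CLUSTER_TYPE_NAMES",
]

#: cluster → dyslexia-type label
CLUSTER_TYPE_NAMES = {
    "Attentional": "Attentional Dyslexia",
    "LetterPosition": "Letter Position Dyslexia",
    "Surface": "Surface Dyslexia",
    "MultiLetter": "Multi-letter Phonological Dyslexia",
    "Vowel": "Vowel Dyslexia",
    "Consonant": "Consonant Dyslexia",
    "Voicing": "Voicing Dyslexia",
    "Doubling": "Doubling (Output Buffer) Dyslexia",
    "Deep": "Deep Dyslexia",
    "Neglect": "Neglect Dyslexia",
}

#: pseudo-labels that norm summary indexes, not clusters
_INDEX_LABELS = {"Total", "SurfaceStressList", "PairsMigrations"}


@dataclass
class DiagnosticProfile:
    child_id: str
    grade: int
    #: (label, list_group) → flagged?
    flags: dict[tuple[str, str], bool] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)
    purity: str = "none"  # none | pure | mixed

    def flagged_clusters(self) -> set[str]:
        """Clusters flagged in any list group (summary indexes excluded)."""
        return {
            label
            for (label, _lg), hit in self.flags.items()
            if hit and label not in _INDEX_LABELS
        }

    @property
    def any_flag(self) -> bool:
        return any(self.flags.values())

    def is_flagged(self, label: str, list_group: str | None = None) -> bool:
        if list_group is not None:
            return self.flags.get((label, list_group), False)
        return any(hit for (lbl, _), hit in self.flags.items() if lbl == label)


def flag_profile(
    score: ClusterScore,
    norms: NormTable,
    inclusive: bool = True,
    surface_requires_stress_view: bool = True,
) -> DiagnosticProfile:
    """Compare one child's scores with the grade's norms and build a profile.

    Fractional scores are compared to the integer threshold without rounding.
    Clusters without a normed cell (Deep and Neglect in the embedded tables,
    Voicing unless computed norms supply it) are never flagged.  The Surface
    Dyslexia label additionally requires the stress-list view to be flagged
    when that view is normed (``surface_requires_stress_view``).
    """
    cells = norms.grade_cells(score.grade)
    profile = DiagnosticProfile(child_id=score.child_id, grade=score.grade)
    for (label, lg), cell in cells.items():
        value = score.norm_value(label, lg)
        hit = value >= cell.threshold if inclusive else value > cell.threshold
        profile.flags[(label, lg)] = bool(hit)

    flagged = profile.flagged_clusters()
    if surface_requires_stress_view and "Surface" in flagged:
        has_view = any(lbl == "SurfaceStressList" for (lbl, _lg) in cells)
        if has_view and not profile.is_flagged("SurfaceStressList"):
            flagged = flagged - {"Surface"}
    if not flagged:
        profile.purity = "none"
    elif len(flagged) == 1:
        profile.purity = "pure"
    else:
        profile.purity = "mixed"
    profile.labels = sorted(CLUSTER_TYPE_NAMES[c] for c in flagged)
    return profile


def selective_sublexical(profile: DiagnosticProfile) -> list[str]:
    """Selective sublexical-route deficit labels derived from the flags.

    * consonant-conversion deficit: Consonant flagged in nonwords only, with
      no Vowel flag anywhere;
    * vowel-conversion deficit: Vowel flagged in nonwords only, with no
      Consonant flag anywhere;
    * Letter Identity Dyslexia (candidate): Consonant flagged in both words
      and nonwords.
    """
    cons_w = profile.is_flagged("Consonant", "words")
    cons_n = profile.is_flagged("Consonant", "nonwords")
    vow_w = profile.is_flagged("Vowel", "words")
    vow_n = profile.is_flagged("Vowel", "nonwords")
    out: list[str] = []
    if cons_n and not cons_w and not vow_w and not vow_n:
        out.append("sublexical consonant-conversion deficit")
    if vow_n and not vow_w and not cons_w and not cons_n:
        out.append("sublexical vowel-conversion deficit")
    if cons_w and cons_n:
        out.append("Letter Identity Dyslexia (candidate)")
    return out


@dataclass(frozen=True)
class AgreementTable:
    both_positive: int
    a_only: int
    b_only: int
    both_negative: int
    chi_square: float
    p: float

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.both_positive, self.a_only, self.b_only, self.both_negative)


def agreement(
    diag_a: Mapping[str, bool] | Sequence[bool],
    diag_b: Mapping[str, bool] | Sequence[bool],
) -> AgreementTable:
    """2×2 agreement between two dichotomous diagnoses of the same children.

    Pearson chi-square without continuity correction, 1 df.  Raises on an
    empty input, on mismatched child sets, and on any zero margin (the
    statistic is undefined there).
    """
    if isinstance(diag_a, Mapping) != isinstance(diag_b, Mapping):
        raise TypeError("diagnoses must both be mappings or both sequences")
    if isinstance(diag_a, Mapping):
        if set(diag_a) != set(diag_b):
            raise ValueError("diagnoses cover different child sets")
        keys = sorted(diag_a)
        a = [bool(diag_a[k]) for k in keys]
        b = [bool(diag_b[k]) for k in keys]
    else:
        if len(diag_a) != len(diag_b):
            raise ValueError("diagnoses have different lengths")
        a, b = [bool(x) for x in diag_a], [bool(x) for x in diag_b]
    if not a:
        raise ValueError("empty diagnosis input")
    pp = sum(1 for x, y in zip(a, b) if x and y)
    a_only = sum(1 for x, y in zip(a, b) if x and not y)
    b_only = sum(1 for x, y in zip(a, b) if not x and y)
    nn = sum(1 for x, y in zip(a, b) if not x and not y)
    return agreement_from_counts(pp, a_only, b_only, nn)


def agreement_from_counts(
    both_positive: int, a_only: int, b_only: int, both_negative: int
) -> AgreementTable:
    """Build the agreement statistic directly from 2×2 counts."""
    table = np.array([[both_positive, a_only], [b_only, both_negative]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, _df, _exp = stats.chi2_contingency(table, correction=False)
    return AgreementTable(both_positive, a_only, b_only, both_negative,
                          float(chi2), float(p))
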