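"""Per-grade normative tables and single-case abnormality thresholds.

Norm construction follows the screening battery's procedure:

1. **Outlier trimming** — within each grade, children whose error count is at
   or above the worst-performing 5% tail (the 95th percentile of the count
   distribution) in at least one of the four indexes (words, pairs, nonwords,
   overall) are removed, so the norms describe unimpaired reading.
2. **Descriptives** — mean ``M``, standard deviation ``SD`` and retained
   ``n`` per grade and per normable quantity.
3. **Single-case threshold** — an individual count ``x`` is compared with a
   small normative sample using the Crawford–Howell t statistic

   .. math:: t = \\frac{x - M}{SD\\,\\sqrt{(n+1)/n}}, \\qquad df = n - 1,

   which corrects the classical z comparison for normative-sample size.  The
   integer abnormality cutoff is the smallest count exceeding the one-sided
   α = 0.005 critical value, computed as
   ``round(M + t_crit(1 - α, n − 1) · SD · sqrt((n+1)/n))`` with
   round-half-away-from-zero, floored at 2 errors (counts below 2 are never
   flagged, however tight the norms).

The reference norms shipped with the package (``data/norms_embedded.csv``)
are a transcription of the published per-grade tables for the word and
nonword lists, with thresholds as printed; ``build_norms`` recomputes the
same structure from any scored cohort, e.g. a synthetic one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from hashlib import sha256
from importlib import resources as _resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormCell",
    "NormTable",
    "DegenerateNormsError",
    "remove_outliers",
    "crawford_howell",
    "cluster_threshold",
    "build_norms",
    "load_embedded_norms",
    "WORD_LABELS",
    "NONWORD_LABELS",
]

_EMBEDDED_SHA256 = "5c2149f460429f434ed5f8790b17c1e27953e77669ce2cb5e3447bf64dcb71ee"

#: normable quantities of the word-list table (list group "words" except the
#: pairs-migration view) and of the nonword-list table
WORD_LABELS = (
    "Attentional", "LetterPosition", "Surface", "MultiLetter", "Vowel",
    "Consonant", "Doubling", "Total", "SurfaceStressList", "PairsMigrations",
)
NONWORD_LABELS = (
    "Attentional", "LetterPosition", "MultiLetter", "Vowel", "Consonant",
    "Doubling", "Total",
)

FOUR_INDEXES = ("words", "pairs", "nonwords", "overall")


class DegenerateNormsError(ValueError):
    """Raised when SD = 0 makes the single-case t statistic undefined."""


@dataclass(frozen=True)
class NormCell:
    grade: int
    label: str
    list_group: str
    M: float
    SD: float
    n: int
    threshold: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"normative n must be >= 2, got {self.n}")
        if self.SD < 0:
            raise ValueError("SD must be nonnegative")
        if self.threshold < 2:
            raise ValueError("threshold below the floor of 2")


@dataclass
class NormTable:
    """grade → (label, list_group) → NormCell."""

    cells: dict[int, dict[tuple[str, str], NormCell]] = field(default_factory=dict)
    provenance: str = "computed"  # or "embedded-paper"

    def add(self, cell: NormCell) -> None:
        self.cells.setdefault(cell.grade, {})[(cell.label, cell.list_group)] = cell

    def get(self, grade: int, label: str, list_group: str) -> NormCell:
        return self.cells[grade][(label, list_group)]

    def grade_cells(self, grade: int) -> dict[tuple[str, str], NormCell]:
        if grade not in self.cells:
            raise KeyError(f"grade {grade} not present in norms")
        return self.cells[grade]

    @property
    def grades(self) -> list[int]:
        return sorted(self.cells)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "grades": {
                str(g): {
                    f"{label}|{lg}": {
                        "M": c.M, "SD": c.SD, "n": c.n, "threshold": c.threshold
                    }
                    for (label, lg), c in cells.items()
                }
                for g, cells in self.cells.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "NormTable":
        table = cls(provenance=d.get("provenance", "computed"))
        for g, cells in d["grades"].items():
            for key, c in cells.items():
                label, lg = key.split("|")
                table.add(NormCell(int(g), label, lg, c["M"], c["SD"],
                                   int(c["n"]), int(c["threshold"])))
        return table


# ---------------------------------------------------------------------------
# outlier trimming
# ---------------------------------------------------------------------------


def remove_outliers(
    index_table: pd.DataFrame,
    tail: float = 0.05,
    percentile_method: str = "linear",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop the worst-performing tail of each grade before norming.

    ``index_table`` has columns ``child_id, grade, words, pairs, nonwords,
    overall``.  Per grade, the cutoff for each of the four indexes is the
    (1 − tail) quantile of the error-count distribution (high counts = poor
    reading); a child at or above the cutoff in one or more indexes is
    removed.  The percentile method defaults to linear interpolation between
    order statistics and accepts any numpy quantile method name.
    """
    required = {"child_id", "grade", *FOUR_INDEXES}
    missing = required - set(index_table.columns)
    if missing:
        raise ValueError(f"index table lacks columns {sorted(missing)}")
    removed: list[str] = []
    keep_rows = []
    for grade, sub in index_table.groupby("grade"):
        if len(sub) == 0:
            raise ValueError(f"empty grade stratum {grade}")
        if len(sub) < 20:
            import warnings

            warnings.warn(
                f"grade {grade}: only {len(sub)} children; norms will be unstable",
                stacklevel=2,
            )
        cutoffs = {
            idx: np.quantile(sub[idx].to_numpy(float), 1 - tail,
                             method=percentile_method)
            for idx in FOUR_INDEXES
        }
        out_mask = np.zeros(len(sub), dtype=bool)
        for idx in FOUR_INDEXES:
            # a zero cutoff would remove error-free readers; only a positive
            # error count can mark the impaired tail
            if cutoffs[idx] > 0:
                out_mask |= sub[idx].to_numpy(float) >= cutoffs[idx]
        removed.extend(sub.loc[out_mask, "child_id"].tolist())
        keep_rows.append(sub.loc[~out_mask])
    retained = pd.concat(keep_rows, ignore_index=True)
    return retained, removed


# ---------------------------------------------------------------------------
# Crawford–Howell single-case statistics
# ---------------------------------------------------------------------------


def crawford_howell(
    x: float, M: float, SD: float, n: int
) -> tuple[float, int, float, float]:
    """Single-case t comparing one observation to a normative sample.

    Returns ``(t, df, p_one_sided, p_two_sided)``; the one-sided p is the
    upper-tail probability (high error counts are the abnormal direction).
    """
    if n < 2:
        raise ValueError("normative sample must have n >= 2")
    if SD <= 0:
        raise DegenerateNormsError("SD must be positive for the single-case t")
    t = (x - M) / (SD * math.sqrt((n + 1) / n))
    df = n - 1
    upper = float(stats.t.sf(t, df))
    p_two = 2 * min(upper, 1 - upper)
    return t, df, upper, p_two


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cluster_threshold(
    M: float,
    SD: float,
    n: int,
    alpha: float = 0.005,
    floor: int = 2,
    two_sided: bool = False,
) -> int:
    """Integer abnormality cutoff for one normative cell.

    ``max(floor, round(M + t_crit · SD · sqrt((n+1)/n)))`` with the critical
    value at ``1 − alpha`` (one-sided upper tail by default; ``two_sided``
    splits alpha) and nearest-integer, half-away-from-zero rounding.  With
    SD = 0 the norms are degenerate and the cutoff falls back to
    ``max(floor, round(M) + 1)`` with a warning.
    """
    if n < 2:
        raise ValueError("normative sample must have n >= 2")
    if SD == 0:
        import warnings

        warnings.warn("SD = 0: degenerate norms, threshold floored", stacklevel=2)
        return max(floor, _round_half_away(M) + 1)
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    tcrit = float(stats.t.ppf(q, n - 1))
    raw = M + tcrit * SD * math.sqrt((n + 1) / n)
    return max(floor, _round_half_away(raw))


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------


def build_norms(
    cohort: pd.DataFrame,
    alpha: float = 0.005,
    floor: int = 2,
    min_n: int = 2,
) -> NormTable:
    """Compute a NormTable from a long-format cohort score table.

    ``cohort`` is the output of :func:`lettura.scoring.cohort_table`
    (columns ``child_id, grade, cluster, list_group, score``), with outliers
    already removed.  One cell is produced per grade × (cluster, list_group)
    present in the table; the sample SD uses ddof = 1.
    """
    table = NormTable(provenance="computed")
    for (grade, label, lg), sub in cohort.groupby(["grade", "cluster", "list_group"]):
        vals = sub["score"].to_numpy(float)
        if len(vals) < min_n:
            raise ValueError(
                f"grade {grade} {label}×{lg}: stratum of {len(vals)} below minimum {min_n}"
            )
        M = float(np.mean(vals))
        SD = float(np.std(vals, ddof=1))
        thr = cluster_threshold(M, SD, len(vals), alpha=alpha, floor=floor)
        table.add(NormCell(int(grade), label, lg, M, SD, len(vals), thr))
    return table


def load_embedded_norms() -> NormTable:
    """Load the packaged reference norms (published Tables, thresholds as
    printed, not recomputed).  Verifies the data file's sha256 checksum."""
    ref = _resources.files("lettura.data").joinpath("norms_embedded.csv")
    raw = ref.read_bytes()
    digest = sha256(raw).hexdigest()
    if digest != _EMBEDDED_SHA256:
        raise RuntimeError(
            f"embedded norms checksum mismatch: {digest} != {_EMBEDDED_SHA256}"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    table = NormTable(provenance="embedded-paper")
    for row in df.itertuples(index=False):
        table.add(
            NormCell(int(row.grade), row.label, row.list_group,
                     float(row.M), float(row.SD), int(row.n), int(row.threshold))
        )
    return table
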