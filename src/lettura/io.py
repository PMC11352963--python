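"""Delimited-text readers/writers and run configuration.

Tabular data travels as UTF-8 delimited text (comma by default, tab
accepted) because transcripts are typically produced by humans in
spreadsheets; norms and diagnostic reports serialise as JSON.  All readers
validate rows and report problems with line numbers; every writer's output
is re-readable by its reader.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from .coding import (
    CodedResponse,
    ErrorCode,
    ErrorType,
    ListId,
    ResponseRecord,
    Source,
    StimulusItem,
    Sublist,
    Unit,
)
from .norming import NormTable
from .orthography import PositionZone
from .scoring import ClusterScore
from .diagnosis import DiagnosticProfile

__all__ = [
    "RunConfig",
    "read_stimuli",
    "write_stimuli",
    "read_transcripts",
    "write_transcripts",
    "write_coded",
    "read_coded",
    "write_norms_json",
    "read_norms_json",
    "profile_report",
    "stress_index_from_marked",
]


@dataclass
class RunConfig:
    """Documented defaults for every statistical convention knob."""

    alpha: float = 0.005
    two_sided: bool = False
    threshold_floor: int = 2
    inclusive_flag: bool = True  # flag when score >= threshold
    percentile_method: str = "linear"
    outlier_tail: float = 0.05
    vowel_migrations_feed_vowel: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def stress_index_from_marked(marked: str, marker: str = "ˈ") -> tuple[str, int]:
    """Convert inline stress-marker notation to (plain text, syllable index).

    The marker precedes the stressed syllable (ˈsabato → syllable 1,
    saˈbato → syllable 2); syllables are counted by vowel nuclei.
    """
    if marker not in marked:
        raise ValueError(f"no stress marker {marker!r} in {marked!r}")
    pre, _, _post = marked.partition(marker)
    plain = marked.replace(marker, "")
    vowels = "aeiouàèéìòù"
    syllable = sum(1 for ch in pre if ch in vowels) + 1
    return plain, syllable


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

_STIM_FIELDS = ["item_id", "text", "list_id", "sublist", "stress_syllable",
                "line_index", "pair_partner"]


def read_stimuli(path: str | Path) -> list[StimulusItem]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(text.splitlines()[0] if text else ",")
    items: list[StimulusItem] = []
    seen: set[str] = set()
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    missing = set(_STIM_FIELDS) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for lineno, row in enumerate(reader, start=2):
        try:
            item = StimulusItem(
                item_id=row["item_id"].strip(),
                text=row["text"].strip().lower(),
                list_id=ListId(row["list_id"].strip()),
                sublist=Sublist(row["sublist"].strip()),
                stress_syllable=int(row["stress_syllable"]) if row["stress_syllable"] else None,
                line_index=int(row["line_index"] or 0),
                pair_partner=row["pair_partner"].strip() or None,
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if item.item_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate item_id {item.item_id!r}")
        seen.add(item.item_id)
        items.append(item)
    for item in items:
        if item.pair_partner is not None and item.pair_partner not in seen:
            raise ValueError(
                f"{path}: item {item.item_id!r} names missing partner "
                f"{item.pair_partner!r}"
            )
    return items


def write_stimuli(items: Sequence[StimulusItem], path: str | Path,
                  delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(_STIM_FIELDS)
        for it in items:
            w.writerow([
                it.item_id, it.text, it.list_id.value, it.sublist.value,
                it.stress_syllable if it.stress_syllable is not None else "",
                it.line_index, it.pair_partner or "",
            ])


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

_TRANS_FIELDS = ["child_id", "grade", "item_id", "response_text",
                 "response_stress", "self_corrected"]


def read_transcripts(
    path: str | Path, items: Sequence[StimulusItem] | None = None
) -> list[ResponseRecord]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(text.splitlines()[0] if text else ",")
    known = {it.item_id for it in items} if items is not None else None
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    missing = set(_TRANS_FIELDS) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[ResponseRecord] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            rec = ResponseRecord(
                child_id=row["child_id"].strip(),
                grade=int(row["grade"]),
                item_id=row["item_id"].strip(),
                response_text=row["response_text"].strip().lower(),
                response_stress=int(row["response_stress"]) if row["response_stress"] else None,
                self_corrected=row["self_corrected"].strip().lower() in ("1", "true", "yes"),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if known is not None and rec.item_id not in known:
            raise ValueError(f"{path}:{lineno}: unknown item_id {rec.item_id!r}")
        out.append(rec)
    return out


def write_transcripts(records: Sequence[ResponseRecord], path: str | Path,
                      delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(_TRANS_FIELDS)
        for r in records:
            w.writerow([
                r.child_id, r.grade, r.item_id, r.response_text,
                r.response_stress if r.response_stress is not None else "",
                int(r.self_corrected),
            ])


# ---------------------------------------------------------------------------
# coded errors
# ---------------------------------------------------------------------------

_CODE_FIELDS = ["child_id", "item_id", "group_id", "etype", "unit", "position",
                "source", "lexicalized", "weight", "detail", "self_corrected"]


def write_coded(coded: Iterable[CodedResponse], path: str | Path,
                delimiter: str = ",") -> None:
    """One row per error code, carrying its alternative-group id and weight."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(_CODE_FIELDS)
        for cr in coded:
            for gid, group in enumerate(cr.groups):
                for code in group:
                    w.writerow([
                        cr.child_id, cr.item_id, gid, code.etype.value,
                        code.unit.value,
                        code.position.value if code.position else "",
                        code.source.value, int(code.lexicalized),
                        str(code.weight), code.detail, int(cr.self_corrected),
                    ])


def read_coded(path: str | Path) -> list[CodedResponse]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(text.splitlines()[0] if text else ",")
    rows = list(csv.DictReader(text.splitlines(), delimiter=delim))
    grouped: dict[tuple[str, str], dict] = {}
    for row in rows:
        key = (row["child_id"], row["item_id"])
        entry = grouped.setdefault(
            key, {"groups": {}, "self_corrected": row["self_corrected"] == "1"}
        )
        code = ErrorCode(
            etype=ErrorType(row["etype"]),
            unit=Unit(row["unit"]),
            position=PositionZone(row["position"]) if row["position"] else None,
            source=Source(row["source"]),
            lexicalized=row["lexicalized"] == "1",
            weight=Fraction(row["weight"]),
            detail=row["detail"],
        )
        entry["groups"].setdefault(int(row["group_id"]), []).append(code)
    out = []
    for (child_id, item_id), entry in grouped.items():
        groups = tuple(
            tuple(entry["groups"][gid]) for gid in sorted(entry["groups"])
        )
        out.append(CodedResponse(item_id, child_id, groups, entry["self_corrected"]))
    return out


# ---------------------------------------------------------------------------
# norms and reports
# ---------------------------------------------------------------------------


def write_norms_json(norms: NormTable, path: str | Path) -> None:
    Path(path).write_text(json.dumps(norms.to_json_dict(), indent=2),
                          encoding="utf-8")


def read_norms_json(path: str | Path) -> NormTable:
    return NormTable.from_json_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def profile_report(
    profile: DiagnosticProfile,
    score: ClusterScore,
    norms: NormTable,
    extra_labels: Sequence[str] = (),
) -> dict:
    """JSON-serialisable diagnostic report: per-cell score vs threshold."""
    cells = norms.grade_cells(profile.grade)
    return {
        "child_id": profile.child_id,
        "grade": profile.grade,
        "purity": profile.purity,
        "labels": list(profile.labels) + list(extra_labels),
        "cells": {
            f"{label}|{lg}": {
                "score": float(score.norm_value(label, lg)),
                "threshold": cell.threshold,
                "flagged": profile.flags[(label, lg)],
            }
            for (label, lg), cell in sorted(cells.items())
        },
    }


def format_report_text(report: dict) -> str:
    lines = [
        f"child {report['child_id']} (grade {report['grade']}): "
        f"{report['purity']}",
    ]
    for key, cell in report["cells"].items():
        mark = " *FLAG*" if cell["flagged"] else ""
        lines.append(
            f"  {key:28s} {cell['score']:6.2f} / threshold {cell['threshold']}{mark}"
        )
    if report["labels"]:
        lines.append("  labels: " + "; ".join(report["labels"]))
    return "\n".join(lines)
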