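"""CSV/JSON readers and writers for corpora, annotations and reports.

All files are UTF-8, comma-separated, with a header row.

corpus CSV      doc_id, hospital_id, <one 0/1 column per variable>
annotations CSV annotator_id, doc_id, variable, label
gold CSV        doc_id, variable, label, provenance
counts CSV      hospital_id, event_documents, total_documents
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation_store import AnnotationSet, GoldStandard, VariableDef
from .document_sampler import DocumentRecord, SampleSelection, SelectionEntry
from .errors import ValidationError
from .evaluator import IaaResult, MetricsResult, render_report
from .slice_calculator import HospitalCorpusCount

__all__ = [
    "ProjectConfig",
    "read_corpus",
    "write_corpus",
    "read_annotations",
    "write_annotations",
    "read_gold",
    "write_gold",
    "read_counts",
    "read_selection",
    "write_selection",
    "write_report",
]

_TRUE_LABELS = {"present", "1", "true", "yes"}
_FALSE_LABELS = {"absent", "0", "false", "no"}


@dataclass(frozen=True)
class ProjectConfig:
    """Project-level settings: variables, significance level, seed."""

    variables: tuple[VariableDef, ...]
    alpha: float = 0.05
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValidationError("variable names must be unique")
        primaries = [v for v in self.variables if v.role == "primary"]
        if len(primaries) != 1:
            raise ValidationError(
                f"exactly one primary variable is required, got {len(primaries)}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def primary_variable(self) -> str:
        return next(v.name for v in self.variables if v.role == "primary")


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise ValidationError(f"file not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise ValidationError(f"file is empty: {path}") from None


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_corpus(
    path: str | Path, variables: Sequence[str] | None = None
) -> list[DocumentRecord]:
    """Read a corpus CSV into DocumentRecords, validating 0/1 flags.

    When ``variables`` is given, the file must contain exactly those flag
    columns; unknown variable columns are an error.
    """
    df = _read_csv(path)
    _require_columns(df, ["doc_id", "hospital_id"], path)
    flag_cols = [c for c in df.columns if c not in ("doc_id", "hospital_id")]
    if variables is not None:
        unknown = sorted(set(flag_cols) - set(variables))
        if unknown:
            raise ValidationError(f"{path}: unknown variable columns {unknown}")
        absent = sorted(set(variables) - set(flag_cols))
        if absent:
            raise ValidationError(f"{path}: missing variable columns {absent}")
        flag_cols = list(variables)
    if not flag_cols:
        raise ValidationError(f"{path}: corpus has no variable flag columns")

    records: list[DocumentRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        doc_id = rowd["doc_id"]
        if doc_id in seen:
            raise ValidationError(f"{path}: duplicate doc_id {doc_id!r} at row {i}")
        seen.add(doc_id)
        flags: dict[str, bool] = {}
        for col in flag_cols:
            value = rowd[col].strip()
            if value not in ("0", "1"):
                raise ValidationError(
                    f"{path}: row {i}: flag {col!r} must be 0 or 1, got {value!r}"
                )
            flags[col] = value == "1"
        records.append(
            DocumentRecord(
                doc_id=doc_id, hospital_id=rowd["hospital_id"], flags=flags
            )
        )
    return records


def write_corpus(records: Sequence[DocumentRecord], path: str | Path) -> None:
    if not records:
        raise ValidationError("cannot write an empty corpus")
    variables = sorted(records[0].flags)
    rows = []
    for rec in records:
        row = {"doc_id": rec.doc_id, "hospital_id": rec.hospital_id}
        for var in variables:
            row[var] = int(rec.flag(var))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_label(raw: str, path, row_no: int) -> bool:
    norm = raw.strip().lower()
    if norm in _TRUE_LABELS:
        return True
    if norm in _FALSE_LABELS:
        return False
    raise ValidationError(
        f"{path}: row {row_no}: label must be present/absent (or 1/0), got {raw!r}"
    )


def read_annotations(path: str | Path) -> dict[str, AnnotationSet]:
    """Read an annotations CSV into one AnnotationSet per annotator.

    Labels are accepted case-insensitively as present/absent or 1/0.
    Duplicate (annotator, doc, variable) rows are an error.
    """
    df = _read_csv(path)
    _require_columns(df, ["annotator_id", "doc_id", "variable", "label"], path)
    sets: dict[str, dict[tuple[str, str], bool]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        ann = rowd["annotator_id"]
        cell = (rowd["doc_id"], rowd["variable"])
        labels = sets.setdefault(ann, {})
        if cell in labels:
            raise ValidationError(
                f"{path}: row {i}: duplicate annotation for annotator {ann!r}, "
                f"doc {cell[0]!r}, variable {cell[1]!r}"
            )
        labels[cell] = _parse_label(rowd["label"], path, i)
    return {
        ann: AnnotationSet(annotator_id=ann, labels=labels)
        for ann, labels in sets.items()
    }


def read_annotation_set(path: str | Path) -> AnnotationSet:
    """Read an annotations CSV expected to contain a single annotator."""
    sets = read_annotations(path)
    if len(sets) != 1:
        raise ValidationError(
            f"{path}: expected a single annotator, found {sorted(sets)}"
        )
    return next(iter(sets.values()))


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    rows = [
        {
            "annotator_id": aset.annotator_id,
            "doc_id": doc,
            "variable": var,
            "label": "present" if present else "absent",
        }
        for (doc, var), present in sorted(aset.labels.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gold(path: str | Path) -> GoldStandard:
    df = _read_csv(path)
    _require_columns(df, ["doc_id", "variable", "label", "provenance"], path)
    labels: dict[tuple[str, str], bool] = {}
    provenance: dict[tuple[str, str], str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        cell = (rowd["doc_id"], rowd["variable"])
        if cell in labels:
            raise ValidationError(
                f"{path}: row {i}: duplicate gold cell {cell!r}"
            )
        labels[cell] = _parse_label(rowd["label"], path, i)
        provenance[cell] = rowd["provenance"].strip()
    return GoldStandard(labels=labels, provenance=provenance)


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    rows = [
        {
            "doc_id": doc,
            "variable": var,
            "label": "present" if gold.labels[(doc, var)] else "absent",
            "provenance": gold.provenance[(doc, var)],
        }
        for (doc, var) in sorted(gold.labels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts(path: str | Path) -> list[HospitalCorpusCount]:
    df = _read_csv(path)
    _require_columns(
        df, ["hospital_id", "event_documents", "total_documents"], path
    )
    counts = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        try:
            event = int(rowd["event_documents"])
            total = int(rowd["total_documents"])
        except ValueError:
            raise ValidationError(
                f"{path}: row {i}: counts must be integers"
            ) from None
        counts.append(
            HospitalCorpusCount(
                hospital_id=rowd["hospital_id"],
                event_documents=event,
                total_documents=total,
            )
        )
    return counts


def read_selection(path: str | Path) -> SampleSelection:
    df = _read_csv(path)
    _require_columns(df, ["doc_id", "hospital_id", "stratum"], path)
    selection = SampleSelection()
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        selection.add(
            SelectionEntry(
                doc_id=rowd["doc_id"],
                hospital_id=rowd["hospital_id"],
                stratum=rowd["stratum"],
            )
        )
    return selection


def write_selection(selection: SampleSelection, path: str | Path) -> None:
    rows = [
        {"doc_id": e.doc_id, "hospital_id": e.hospital_id, "stratum": e.stratum}
        for e in selection.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(
    results: Sequence[MetricsResult | IaaResult],
    path: str | Path,
    format: str = "json",
) -> None:
    Path(path).write_text(render_report(results, format=format), encoding="utf-8")


def read_report_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
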