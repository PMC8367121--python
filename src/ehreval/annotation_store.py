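"""Blind double annotation, disagreement extraction and curator adjudication.

Two annotators independently label every selected document for every
variable as present/absent.  Cells where they agree enter the gold
standard as consensus; the remaining cells are decided by a curator, whose
labels are recorded with provenance "curated".  The default dialect is an
explicit grid: a missing cell is a validation error, because silently
treating absence-of-a-row as an absent label is the classic
corpus-construction bug.  A lenient dialect that does read missing cells
as absent is available behind a flag in the IO layer.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError

__all__ = [
    "VariableDef",
    "AnnotationRecord",
    "AnnotationSet",
    "GoldStandard",
    "find_disagreements",
    "build_gold",
]

Cell = tuple[str, str]  # (doc_id, variable)


@dataclass(frozen=True)
class VariableDef:
    name: str
    role: str  # "primary" | "secondary"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("variable name must be non-empty")
        if self.role not in ("primary", "secondary"):
            raise ValidationError(
                f"variable role must be 'primary' or 'secondary', got {self.role!r}"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    annotator_id: str
    doc_id: str
    variable: str
    label: str  # "present" | "absent"

    def __post_init__(self) -> None:
        if self.label not in ("present", "absent"):
            raise ValidationError(
                f"label must be 'present' or 'absent', got {self.label!r} "
                f"(annotator {self.annotator_id!r}, doc {self.doc_id!r}, "
                f"variable {self.variable!r})"
            )

    @property
    def present(self) -> bool:
        return self.label == "present"


@dataclass
class AnnotationSet:
    """One annotator's labels over a document x variable grid."""

    annotator_id: str
    labels: dict[Cell, bool] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, annotator_id: str, records: Iterable[AnnotationRecord]
    ) -> "AnnotationSet":
        labels: dict[Cell, bool] = {}
        for rec in records:
            if rec.annotator_id != annotator_id:
                continue
            cell = (rec.doc_id, rec.variable)
            if cell in labels:
                raise ValidationError(
                    f"duplicate annotation for annotator {annotator_id!r}, "
                    f"doc {cell[0]!r}, variable {cell[1]!r}"
                )
            labels[cell] = rec.present
        return cls(annotator_id=annotator_id, labels=labels)

    @property
    def grid(self) -> frozenset[Cell]:
        return frozenset(self.labels)

    def variables(self) -> set[str]:
        return {v for (_, v) in self.labels}

    def doc_ids(self) -> set[str]:
        return {d for (d, _) in self.labels}


@dataclass
class GoldStandard:
    """Adjudicated document-level truth with per-cell provenance."""

    labels: dict[Cell, bool]
    provenance: dict[Cell, str]  # "consensus" | "curated"

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.provenance):
            raise ValidationError("labels and provenance must cover the same grid")
        for cell, prov in self.provenance.items():
            if prov not in ("consensus", "curated"):
                raise ValidationError(
                    f"provenance must be 'consensus' or 'curated', got "
                    f"{prov!r} at cell {cell!r}"
                )

    @property
    def grid(self) -> frozenset[Cell]:
        return frozenset(self.labels)

    def variables(self) -> set[str]:
        return {v for (_, v) in self.labels}


def _check_same_grid(a: AnnotationSet, b: AnnotationSet) -> None:
    if a.grid != b.grid:
        missing_in_b = sorted(a.grid - b.grid)
        missing_in_a = sorted(b.grid - a.grid)
        parts = []
        if missing_in_b:
            parts.append(f"cells missing from {b.annotator_id!r}: {missing_in_b[:10]}")
        if missing_in_a:
            parts.append(f"cells missing from {a.annotator_id!r}: {missing_in_a[:10]}")
        raise ValidationError("annotation grids differ; " + "; ".join(parts))


def find_disagreements(a: AnnotationSet, b: AnnotationSet) -> list[Cell]:
    """Cells where the two annotators assign different labels.

    Returned in deterministic (doc_id, variable) sort order.
    """
    _check_same_grid(a, b)
    return sorted(cell for cell in a.grid if a.labels[cell] != b.labels[cell])


def build_gold(
    a: AnnotationSet,
    b: AnnotationSet,
    curator: Mapping[Cell, bool] | None = None,
) -> GoldStandard:
    """Merge two blind annotation sets into a gold standard.

    Agreement cells take the shared label (provenance "consensus").  Every
    disagreement cell must carry a curator label (provenance "curated");
    a missing one is an error.  Curator labels on agreement cells are
    ignored with a warning: the curator's mandate covers only the
    disagreements.
    """
    curator = dict(curator or {})
    disagreements = set(find_disagreements(a, b))

    labels: dict[Cell, bool] = {}
    provenance: dict[Cell, str] = {}
    for cell in sorted(a.grid):
        if cell in disagreements:
            if cell not in curator:
                raise ValidationError(
                    f"curator label missing for disagreement cell {cell!r}"
                )
            labels[cell] = bool(curator[cell])
            provenance[cell] = "curated"
        else:
            labels[cell] = a.labels[cell]
            provenance[cell] = "consensus"

    extraneous = sorted(set(curator) - disagreements)
    for cell in extraneous:
        _warnings.warn(
            f"curator label for agreement cell {cell!r} ignored",
            stacklevel=2,
        )
    return GoldStandard(labels=labels, provenance=provenance)
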