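"""Seeded stratified selection of documents for the gold standard.

The primary variable's positives and negatives are drawn per hospital
according to the calculator's quotas; secondary variables are then
represented by topping up with documents flagged positive for each of
them, and (optionally) negatives drawn only from documents whose primary
flag is false.  Secondary quotas are representation targets, not
statistical guarantees: shortfalls are recorded as warnings, never errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleSamplingError, ValidationError

__all__ = [
    "DocumentRecord",
    "PrimaryQuota",
    "SecondaryQuota",
    "SamplingPlan",
    "SelectionEntry",
    "SampleSelection",
    "sample_primary",
    "sample_secondary",
]


@dataclass(frozen=True)
class DocumentRecord:
    """One document's identity plus per-variable pre-annotation flags."""

    doc_id: str
    hospital_id: str
    flags: Mapping[str, bool]

    def flag(self, variable: str) -> bool:
        if variable not in self.flags:
            raise ValidationError(
                f"document {self.doc_id!r} has no flag for variable {variable!r}"
            )
        return bool(self.flags[variable])


@dataclass(frozen=True)
class PrimaryQuota:
    positives: int
    negatives: int

    def __post_init__(self) -> None:
        if self.positives < 0 or self.negatives < 0:
            raise ValidationError("primary quotas must be non-negative")


@dataclass(frozen=True)
class SecondaryQuota:
    min_positives: int = 20
    min_negatives: int = 0

    def __post_init__(self) -> None:
        if self.min_positives < 0 or self.min_negatives < 0:
            raise ValidationError("secondary quotas must be non-negative")


@dataclass(frozen=True)
class SamplingPlan:
    """Quotas and seed driving a reproducible selection."""

    primary_variable: str
    per_hospital: Mapping[str, PrimaryQuota]
    secondary: Mapping[str, SecondaryQuota] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class SelectionEntry:
    doc_id: str
    hospital_id: str
    stratum: str


@dataclass
class SampleSelection:
    entries: list[SelectionEntry] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def doc_ids(self) -> set[str]:
        return {e.doc_id for e in self.entries}

    def add(self, entry: SelectionEntry) -> None:
        if entry.doc_id in self.doc_ids:
            raise ValidationError(
                f"document {entry.doc_id!r} already selected; selections "
                f"must not contain duplicates"
            )
        self.entries.append(entry)


def _check_corpus(corpus: Sequence[DocumentRecord]) -> None:
    if not corpus:
        raise ValidationError("corpus must be non-empty")
    seen: set[str] = set()
    for rec in corpus:
        if rec.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {rec.doc_id!r} in corpus")
        seen.add(rec.doc_id)


def _draw(rng: np.random.Generator, pool: list[DocumentRecord], k: int):
    """Uniform draw of k documents without replacement, deterministic for a
    given generator state; pool order is normalized by doc_id first."""
    pool = sorted(pool, key=lambda r: r.doc_id)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(int(i) for i in idx)]


def sample_primary(
    corpus: Sequence[DocumentRecord], plan: SamplingPlan
) -> SampleSelection:
    """Draw the primary variable's positives and negatives per hospital.

    Raises ``InfeasibleSamplingError`` if any hospital cannot supply its
    quota.  Identical corpus + plan (including seed) always yields the
    identical selection.
    """
    _check_corpus(corpus)
    rng = np.random.default_rng(plan.seed)
    selection = SampleSelection()
    var = plan.primary_variable

    by_hospital: dict[str, list[DocumentRecord]] = {}
    for rec in corpus:
        by_hospital.setdefault(rec.hospital_id, []).append(rec)

    for hospital_id in sorted(plan.per_hospital):
        quota = plan.per_hospital[hospital_id]
        docs = by_hospital.get(hospital_id, [])
        positives = [d for d in docs if d.flag(var)]
        negatives = [d for d in docs if not d.flag(var)]
        if len(positives) < quota.positives:
            raise InfeasibleSamplingError(
                hospital_id, "primary-positive", len(positives), quota.positives
            )
        if len(negatives) < quota.negatives:
            raise InfeasibleSamplingError(
                hospital_id, "primary-negative", len(negatives), quota.negatives
            )
        for rec in _draw(rng, positives, quota.positives):
            selection.add(
                SelectionEntry(rec.doc_id, rec.hospital_id, "primary-positive")
            )
        for rec in _draw(rng, negatives, quota.negatives):
            selection.add(
                SelectionEntry(rec.doc_id, rec.hospital_id, "primary-negative")
            )
    return selection


def sample_secondary(
    corpus: Sequence[DocumentRecord],
    selection: SampleSelection,
    plan: SamplingPlan,
) -> SampleSelection:
    """Top up the primary selection so each secondary variable is represented.

    Positives already inside the selection count toward each variable's
    ``min_positives``; only the shortfall triggers new draws from that
    variable's positive stratum.  Secondary negatives are drawn exclusively
    from documents whose primary flag is false.  Exhausted strata are
    logged in ``selection.warnings``.
    """
    _check_corpus(corpus)
    # independent stream so primary draws are unaffected by secondary config
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 1]))
    by_id = {rec.doc_id: rec for rec in corpus}
    primary = plan.primary_variable

    for var in sorted(plan.secondary):
        quota = plan.secondary[var]

        have_pos = sum(
            1 for e in selection.entries if by_id[e.doc_id].flag(var)
        )
        shortfall = quota.min_positives - have_pos
        if shortfall > 0:
            pool = [
                rec
                for rec in corpus
                if rec.flag(var) and rec.doc_id not in selection.doc_ids
            ]
            take = min(shortfall, len(pool))
            if take < shortfall:
                selection.warnings.append(
                    f"secondary:{var}:positive stratum exhausted: wanted "
                    f"{shortfall} more, only {take} available"
                )
            for rec in _draw(rng, pool, take):
                selection.add(
                    SelectionEntry(
                        rec.doc_id, rec.hospital_id, f"secondary:{var}:positive"
                    )
                )

        have_neg = sum(
            1
            for e in selection.entries
            if not by_id[e.doc_id].flag(var) and not by_id[e.doc_id].flag(primary)
        )
        shortfall = quota.min_negatives - have_neg
        if shortfall > 0:
            pool = [
                rec
                for rec in corpus
                if not rec.flag(var)
                and not rec.flag(primary)
                and rec.doc_id not in selection.doc_ids
            ]
            take = min(shortfall, len(pool))
            if take < shortfall:
                selection.warnings.append(
                    f"secondary:{var}:negative stratum exhausted: wanted "
                    f"{shortfall} more, only {take} available"
                )
            for rec in _draw(rng, pool, take):
                selection.add(
                    SelectionEntry(
                        rec.doc_id, rec.hospital_id, f"secondary:{var}:negative"
                    )
                )
    return selection
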