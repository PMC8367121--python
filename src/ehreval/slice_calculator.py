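"""SLiCE-style sample-size calculation for gold-standard construction.

Given a desired confidence level, a confidence-interval half-width, the
expected precision and recall of the system under evaluation, and the
occurrence rate (frequency) of the primary clinical variable, the
calculator returns how many positive and negative documents the gold
standard needs, and how to share them equally among participating
hospitals.

"Positive" documents are those the system's pre-annotation flags as
mentioning the variable; "negative" documents are unflagged.  The sizing
logic (see docs/methods.md for the full derivation):

* ``N_R`` -- the smallest denominator for which the Clopper-Pearson
  interval around the expected recall is no wider than twice the requested
  half-width; the recall estimate needs this many truly-positive documents.
* ``N_P`` -- the analogous denominator for the expected precision; the
  precision estimate is computed over flagged documents.
* ``n_positive = max(round(N_R * R / P), N_P)`` -- flagged documents whose
  expected truly-positive yield ``P * n_positive`` supplies the detected
  share ``R * N_R`` of the recall denominator, and which in any case
  suffice for the precision interval.
* ``n_total = round(N_P / (P * f))`` -- with flag rate ``f`` and flag
  precision ``P`` a randomly drawn document is a correctly-flagged positive
  with probability ``P * f``, so this corpus size is needed for ``N_P``
  correctly-flagged documents; the remainder after the positive stratum is
  the negative stratum, which supplies the false-negative share of the
  recall denominator and keeps the sample's composition anchored to the
  corpus frequency.

Low-frequency variables therefore demand many more negative documents,
and optimistic precision/recall expectations shrink the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import beta as _beta

from .errors import SampleSizeCapError, ValidationError

__all__ = [
    "HospitalCorpusCount",
    "SliceRequest",
    "HospitalAllocation",
    "SliceResult",
    "internal_frequency",
    "min_n_for_width",
    "allocate_to_hospitals",
    "compute_sample_size",
]

DEFAULT_SEARCH_CAP = 1_000_000


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class HospitalCorpusCount:
    """Per-hospital corpus tallies used to derive the internal frequency."""

    hospital_id: str
    event_documents: int
    total_documents: int

    def __post_init__(self) -> None:
        if self.total_documents < 1:
            raise ValidationError(
                f"total_documents must be >= 1 for hospital "
                f"{self.hospital_id!r}, got {self.total_documents}"
            )
        if not 0 <= self.event_documents <= self.total_documents:
            raise ValidationError(
                f"event_documents must be in [0, total_documents] for hospital "
                f"{self.hospital_id!r}, got {self.event_documents}"
            )

    @property
    def rate(self) -> float:
        return self.event_documents / self.total_documents


@dataclass(frozen=True)
class SliceRequest:
    """Inputs to the sample-size calculator."""

    expected_precision: float
    expected_recall: float
    frequency: float
    confidence_level: float = 0.95
    half_width: float = 0.05
    frequency_mode: str = "external"
    n_hospitals: int = 1

    def __post_init__(self) -> None:
        for name in ("expected_precision", "expected_recall", "frequency"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValidationError(
                f"confidence_level must be in (0, 1), got {self.confidence_level}"
            )
        if not 0.0 < self.half_width < 0.5:
            raise ValidationError(
                f"half_width must be in (0, 0.5), got {self.half_width}"
            )
        if self.frequency_mode not in ("internal", "external"):
            raise ValidationError(
                f"frequency_mode must be 'internal' or 'external', "
                f"got {self.frequency_mode!r}"
            )
        if self.n_hospitals < 1:
            raise ValidationError(
                f"n_hospitals must be >= 1, got {self.n_hospitals}"
            )

    @property
    def alpha(self) -> float:
        return 1.0 - self.confidence_level


@dataclass(frozen=True)
class HospitalAllocation:
    hospital_index: int
    positives: int
    negatives: int

    @property
    def documents(self) -> int:
        return self.positives + self.negatives


@dataclass(frozen=True)
class SliceResult:
    n_positive: int
    n_negative: int
    per_hospital: tuple[HospitalAllocation, ...] = field(default_factory=tuple)

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative

    def as_dict(self) -> dict:
        return {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_total": self.n_total,
            "per_hospital": [
                {
                    "hospital_index": h.hospital_index,
                    "positives": h.positives,
                    "negatives": h.negatives,
                    "documents": h.documents,
                }
                for h in self.per_hospital
            ],
        }


def internal_frequency(counts: Sequence[HospitalCorpusCount]) -> float:
    """Occurrence rate of the main variable, averaged over hospitals.

    The final frequency is the unweighted mean of each hospital's
    ``event_documents / total_documents`` ratio, so every participating
    site contributes equally regardless of corpus size.
    """
    counts = list(counts)
    if not counts:
        raise ValidationError("counts must be a non-empty list of hospital tallies")
    return float(np.mean([c.rate for c in counts]))


def _cp_widths(r: np.ndarray, n: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized Clopper-Pearson widths for arrays of (r, n)."""
    half = alpha / 2.0
    lower = np.where(r == 0, 0.0, _beta.ppf(half, np.maximum(r, 1), n - r + 1))
    upper = np.where(
        r == n, 1.0, _beta.ppf(1.0 - half, r + 1, np.maximum(n - r, 1))
    )
    return upper - lower


def min_n_for_width(
    p_expected: float,
    half_width: float,
    alpha: float = 0.05,
    cap: int = DEFAULT_SEARCH_CAP,
) -> int:
    """Smallest n whose Clopper-Pearson interval at the expected proportion
    is no wider than ``2 * half_width``.

    The expected success count at each n is ``round(p_expected * n)`` with
    .5 rounding up.  The search is a linear scan from n = 1 (evaluated in
    vectorized blocks); exceeding ``cap`` raises ``SampleSizeCapError``.
    """
    if not 0.0 < p_expected < 1.0:
        raise ValidationError(f"p_expected must be in (0, 1), got {p_expected}")
    if not 0.0 < half_width < 0.5:
        raise ValidationError(f"half_width must be in (0, 0.5), got {half_width}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    target = 2.0 * half_width
    block = 1024
    start = 1
    while start <= cap:
        stop = min(start + block - 1, cap)
        n = np.arange(start, stop + 1)
        r = np.floor(p_expected * n + 0.5).astype(int)
        ok = _cp_widths(r, n, alpha) <= target
        if ok.any():
            return int(n[int(np.argmax(ok))])
        start = stop + 1
    raise SampleSizeCapError(cap, p_expected, half_width)


def allocate_to_hospitals(
    n_positive: int, n_negative: int, k: int
) -> tuple[HospitalAllocation, ...]:
    """Share the totals equally among k hospitals, rounding up per class.

    Each hospital receives ``ceil(n_positive / k)`` positives and
    ``ceil(n_negative / k)`` negatives, so summed allocations may slightly
    exceed the requested totals (a deliberate over-coverage: every site
    annotates the same, sufficient amount).
    """
    if k < 1:
        raise ValidationError(f"number of hospitals must be >= 1, got {k}")
    if n_positive < 0 or n_negative < 0:
        raise ValidationError("allocation counts must be non-negative")
    pos = math.ceil(n_positive / k)
    neg = math.ceil(n_negative / k)
    return tuple(
        HospitalAllocation(hospital_index=i, positives=pos, negatives=neg)
        for i in range(k)
    )


def compute_sample_size(
    request: SliceRequest,
    counts: Optional[Iterable[HospitalCorpusCount]] = None,
    cap: int = DEFAULT_SEARCH_CAP,
) -> SliceResult:
    """Number of positive and negative documents the gold standard needs.

    With ``frequency_mode="internal"`` the request's frequency is replaced
    by the per-hospital average computed from ``counts``; with
    ``"external"`` the supplied frequency is used verbatim.
    """
    if request.frequency_mode == "internal":
        if counts is None:
            raise ValidationError(
                "frequency_mode='internal' requires per-hospital counts"
            )
        freq = internal_frequency(list(counts))
        if not 0.0 < freq < 1.0:
            raise ValidationError(
                f"internal frequency must be in (0, 1), got {freq}"
            )
    else:
        freq = request.frequency

    alpha = request.alpha
    p = request.expected_precision
    r = request.expected_recall

    n_prec = min_n_for_width(p, request.half_width, alpha, cap=cap)
    n_rec = min_n_for_width(r, request.half_width, alpha, cap=cap)

    n_positive = max(_round_half_up(n_rec * r / p), n_prec)
    n_total = _round_half_up(n_prec / (p * freq))
    n_negative = max(n_total - n_positive, 0)

    per_hospital = allocate_to_hospitals(
        n_positive, n_negative, request.n_hospitals
    )
    return SliceResult(
        n_positive=n_positive,
        n_negative=n_negative,
        per_hospital=per_hospital,
    )
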