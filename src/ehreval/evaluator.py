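"""Precision/recall/F1 evaluation with exact confidence intervals.

Evaluation is at the document level, per variable: a prediction set is
compared against the adjudicated gold standard to obtain a confusion
table, and precision = TP/(TP+FP), recall = TP/(TP+FN) and their harmonic
mean F1 are reported with Clopper-Pearson intervals.  Inter-annotator
agreement (IAA) is the F1 of one annotator's labels against the other's,
which is symmetric under swapping (precision and recall exchange and the
harmonic mean is invariant); Cohen's kappa is deliberately not offered.

The F1 interval is constructed as the harmonic mean of the respective
precision and recall bounds (lower from the lowers, upper from the
uppers).  F1 has no exact binomial interval; this construction is
conservative-in-shape and keeps the three intervals mutually consistent.

Zero-denominator conventions: an empty denominator reports the metric as
0.0 with its ``defined`` flag set to False (never an exception); F1 is 0
whenever either component is 0.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .annotation_store import AnnotationSet, GoldStandard
from .binomial_ci import BinomialSample, ConfidenceInterval, clopper_pearson
from .errors import ValidationError
from .slice_calculator import SliceRequest

__all__ = [
    "ConfusionCounts",
    "MetricsResult",
    "IaaResult",
    "ComplianceReport",
    "confusion",
    "metrics",
    "iaa",
    "check_expected_compliance",
    "render_report",
    "harmonic_f1",
    "round_half_up_2dp",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsResult:
    variable: str
    precision: float
    precision_ci: ConfidenceInterval
    precision_defined: bool
    recall: float
    recall_ci: ConfidenceInterval
    recall_defined: bool
    f1: float
    f1_ci: ConfidenceInterval
    counts: ConfusionCounts


@dataclass(frozen=True)
class IaaResult:
    variable: str
    f1: float
    f1_ci: ConfidenceInterval
    counts: ConfusionCounts


@dataclass(frozen=True)
class ComplianceReport:
    """Achieved CI widths and point estimates against the sizing request."""

    variable: str
    precision_width: float
    recall_width: float
    max_allowed_width: float
    precision_width_ok: bool
    recall_width_ok: bool
    precision_meets_expected: bool
    recall_meets_expected: bool


def harmonic_f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 if either is 0."""
    if precision <= 0.0 or recall <= 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def round_half_up_2dp(x: float) -> float:
    """Display rounding to 2 decimals with .005 rounding up."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion(
    gold: GoldStandard, predictions: AnnotationSet, variable: str
) -> ConfusionCounts:
    """Per-variable confusion table of predictions against the gold labels."""
    cells = sorted(c for c in gold.grid if c[1] == variable)
    if not cells:
        raise ValidationError(f"gold standard has no cells for variable {variable!r}")
    missing = [c for c in cells if c not in predictions.labels]
    if missing:
        raise ValidationError(
            f"predictions do not cover the gold grid for variable "
            f"{variable!r}; missing cells: {missing[:10]}"
        )
    tp = fp = fn = tn = 0
    for cell in cells:
        g, p = gold.labels[cell], predictions.labels[cell]
        if g and p:
            tp += 1
        elif not g and p:
            fp += 1
        elif g and not p:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _proportion_with_ci(
    successes: int, trials: int, alpha: float
) -> tuple[float, ConfidenceInterval, bool]:
    if trials == 0:
        return 0.0, ConfidenceInterval(0.0, 1.0, 1.0 - alpha), False
    value = successes / trials
    ci = clopper_pearson(BinomialSample(successes, trials), alpha)
    return value, ci, True


def metrics(
    counts: ConfusionCounts, alpha: float = 0.05, variable: str = ""
) -> MetricsResult:
    """Precision, recall and F1 with Clopper-Pearson intervals."""
    precision, p_ci, p_def = _proportion_with_ci(
        counts.tp, counts.tp + counts.fp, alpha
    )
    recall, r_ci, r_def = _proportion_with_ci(
        counts.tp, counts.tp + counts.fn, alpha
    )
    f1 = harmonic_f1(precision, recall)
    f1_ci = ConfidenceInterval(
        lower=harmonic_f1(p_ci.lower, r_ci.lower),
        upper=harmonic_f1(p_ci.upper, r_ci.upper),
        level=1.0 - alpha,
    )
    return MetricsResult(
        variable=variable,
        precision=precision,
        precision_ci=p_ci,
        precision_defined=p_def,
        recall=recall,
        recall_ci=r_ci,
        recall_defined=r_def,
        f1=f1,
        f1_ci=f1_ci,
        counts=counts,
    )


def iaa(
    a: AnnotationSet,
    b: AnnotationSet,
    variable: str,
    alpha: float = 0.05,
) -> IaaResult:
    """Inter-annotator agreement for one variable, as pairwise F1.

    One annotator is treated as reference and the other as prediction;
    swapping them exchanges precision and recall and leaves F1 unchanged.
    """
    cells = sorted(c for c in a.grid if c[1] == variable)
    if not cells:
        raise ValidationError(f"annotation sets have no cells for {variable!r}")
    ref = GoldStandard(
        labels={c: a.labels[c] for c in cells},
        provenance={c: "consensus" for c in cells},
    )
    restricted_b = AnnotationSet(
        annotator_id=b.annotator_id,
        labels={c: b.labels[c] for c in cells if c in b.labels},
    )
    counts = confusion(ref, restricted_b, variable)
    m = metrics(counts, alpha=alpha, variable=variable)
    return IaaResult(variable=variable, f1=m.f1, f1_ci=m.f1_ci, counts=counts)


def check_expected_compliance(
    result: MetricsResult, request: SliceRequest
) -> ComplianceReport:
    """Did the evaluation deliver the CI widths and performance it was sized for?"""
    max_width = 2.0 * request.half_width
    return ComplianceReport(
        variable=result.variable,
        precision_width=result.precision_ci.width,
        recall_width=result.recall_ci.width,
        max_allowed_width=max_width,
        precision_width_ok=result.precision_ci.width <= max_width,
        recall_width_ok=result.recall_ci.width <= max_width,
        precision_meets_expected=result.precision >= request.expected_precision,
        recall_meets_expected=result.recall >= request.expected_recall,
    )


def _fmt(value: float, ci: ConfidenceInterval) -> str:
    return (
        f"{round_half_up_2dp(value):.2f} "
        f"({round_half_up_2dp(ci.lower):.2f}-{round_half_up_2dp(ci.upper):.2f})"
    )


def report_records(
    results: Sequence[MetricsResult | IaaResult],
) -> list[dict]:
    """Full-precision, JSON-serializable records for a list of results."""
    records = []
    for res in results:
        if not res.variable:
            raise ValidationError("result has an empty variable name")
        if isinstance(res, MetricsResult):
            records.append(
                {
                    "variable": res.variable,
                    "kind": "metrics",
                    "precision": res.precision,
                    "precision_lower": res.precision_ci.lower,
                    "precision_upper": res.precision_ci.upper,
                    "precision_defined": res.precision_defined,
                    "recall": res.recall,
                    "recall_lower": res.recall_ci.lower,
                    "recall_upper": res.recall_ci.upper,
                    "recall_defined": res.recall_defined,
                    "f1": res.f1,
                    "f1_lower": res.f1_ci.lower,
                    "f1_upper": res.f1_ci.upper,
                    "tp": res.counts.tp,
                    "fp": res.counts.fp,
                    "fn": res.counts.fn,
                    "tn": res.counts.tn,
                }
            )
        elif isinstance(res, IaaResult):
            records.append(
                {
                    "variable": res.variable,
                    "kind": "iaa",
                    "f1": res.f1,
                    "f1_lower": res.f1_ci.lower,
                    "f1_upper": res.f1_ci.upper,
                    "tp": res.counts.tp,
                    "fp": res.counts.fp,
                    "fn": res.counts.fn,
                    "tn": res.counts.tn,
                }
            )
        else:
            raise ValidationError(
                f"unsupported result type {type(res).__name__}"
            )
    return records


def render_report(
    results: Sequence[MetricsResult | IaaResult], format: str = "markdown"
) -> str:
    """Per-variable report rows in the "estimate (lower-upper)" style.

    ``csv`` and ``markdown`` round half-up to 2 decimals for display;
    ``json`` keeps full precision and round-trips losslessly through
    ``json.loads``.
    """
    if not results:
        raise ValidationError("cannot render an empty report")
    if format == "json":
        return json.dumps(report_records(results), indent=2)
    if format not in ("csv", "markdown"):
        raise ValidationError(
            f"unknown report format {format!r}; expected csv, json or markdown"
        )

    rows = []
    for res in results:
        if not res.variable:
            raise ValidationError("result has an empty variable name")
        if isinstance(res, MetricsResult):
            rows.append(
                {
                    "variable": res.variable,
                    "precision": _fmt(res.precision, res.precision_ci),
                    "recall": _fmt(res.recall, res.recall_ci),
                    "f1": _fmt(res.f1, res.f1_ci),
                }
            )
        else:
            rows.append(
                {
                    "variable": res.variable,
                    "precision": "",
                    "recall": "",
                    "f1": _fmt(res.f1, res.f1_ci),
                }
            )

    if format == "csv":
        buf = _io.StringIO()
        writer = csv.DictWriter(
            buf, fieldnames=["variable", "precision", "recall", "f1"]
        )
        writer.writeheader()
        writer.writerows(rows)
        return buf.getvalue()

    header = "| Variable | Precision (CI) | Recall (CI) | F1 (CI) |"
    sep = "| --- | --- | --- | --- |"
    lines = [header, sep]
    for row in rows:
        lines.append(
            f"| {row['variable']} | {row['precision']} | {row['recall']} "
            f"| {row['f1']} |"
        )
    return "\n".join(lines) + "\n"
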