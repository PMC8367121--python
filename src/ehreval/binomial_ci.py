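"""Exact (Clopper-Pearson) binomial confidence intervals.

The Clopper-Pearson interval inverts the binomial tail probabilities and is
the numerical core of both the gold-standard sample-size calculator and the
precision/recall evaluator.  Two equivalent computational routes are
provided: the inverse regularized incomplete Beta function (the default) and
the F-distribution form

    lower = r / (r + (n - r + 1) * F_{1-a/2}(2(n-r+1), 2r))
    upper = (r+1) * F_{1-a/2}(2(r+1), 2(n-r))
            / ((n-r) + (r+1) * F_{1-a/2}(2(r+1), 2(n-r)))

which agree to floating-point accuracy; the F route is kept as a
verification path.  All proportions live in [0, 1]; rendering as
percentages is the concern of the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta as _beta
from scipy.stats import f as _fdist

from .errors import ValidationError

__all__ = [
    "BinomialSample",
    "ConfidenceInterval",
    "clopper_pearson",
    "interval_width",
]


@dataclass(frozen=True)
class BinomialSample:
    """r successes observed in n independent trials."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if not isinstance(self.trials, (int,)) or isinstance(self.trials, bool):
            raise ValidationError(f"trials must be an integer, got {self.trials!r}")
        if not isinstance(self.successes, (int,)) or isinstance(self.successes, bool):
            raise ValidationError(
                f"successes must be an integer, got {self.successes!r}"
            )
        if self.trials < 1:
            raise ValidationError(f"trials must be >= 1, got {self.trials}")
        if self.successes < 0:
            raise ValidationError(f"successes must be >= 0, got {self.successes}")
        if self.successes > self.trials:
            raise ValidationError(
                f"successes ({self.successes}) exceeds trials ({self.trials})"
            )

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class ConfidenceInterval:
    """A two-sided confidence interval for a proportion, at level 1 - alpha."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValidationError(
                f"interval bounds must satisfy 0 <= lower <= upper <= 1, "
                f"got ({self.lower}, {self.upper})"
            )
        if not 0.0 < self.level < 1.0:
            raise ValidationError(f"level must be in (0, 1), got {self.level}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, p: float) -> bool:
        return self.lower <= p <= self.upper


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")


def clopper_pearson(
    sample: BinomialSample, alpha: float = 0.05, method: str = "beta"
) -> ConfidenceInterval:
    """Exact two-sided Clopper-Pearson interval for ``sample``.

    Parameters
    ----------
    sample : BinomialSample
        Observed successes over trials.
    alpha : float
        Significance level; the interval has confidence ``1 - alpha``.
    method : {"beta", "f"}
        "beta" inverts the regularized incomplete Beta function;
        "f" uses the F-distribution formulation.  Both agree to ~1e-12.

    Notes
    -----
    r = 0 forces lower = 0 and r = n forces upper = 1; those one-sided
    limits are returned in closed form rather than through a quantile call
    with a zero shape parameter.
    """
    _check_alpha(alpha)
    if method not in ("beta", "f"):
        raise ValidationError(f"unknown method {method!r}; expected 'beta' or 'f'")
    r, n = sample.successes, sample.trials
    half = alpha / 2.0

    if r == 0:
        lower = 0.0
    elif method == "beta":
        lower = float(_beta.ppf(half, r, n - r + 1))
    else:
        fq = float(_fdist.ppf(1.0 - half, 2 * (n - r + 1), 2 * r))
        lower = r / (r + (n - r + 1) * fq)

    if r == n:
        upper = 1.0
    elif method == "beta":
        upper = float(_beta.ppf(1.0 - half, r + 1, n - r))
    else:
        fq = float(_fdist.ppf(1.0 - half, 2 * (r + 1), 2 * (n - r)))
        upper = (r + 1) * fq / ((n - r) + (r + 1) * fq)

    # quantile round-off can nudge bounds out of [0, 1] by ~1e-16
    lower = min(max(lower, 0.0), 1.0)
    upper = min(max(upper, 0.0), 1.0)
    return ConfidenceInterval(lower=lower, upper=upper, level=1.0 - alpha)


def interval_width(sample: BinomialSample, alpha: float = 0.05) -> float:
    """Width (upper - lower) of the Clopper-Pearson interval."""
    ci = clopper_pearson(sample, alpha)
    return ci.width
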