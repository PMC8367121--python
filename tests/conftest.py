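import math

import numpy as np
import pytest
from scipy.stats import binom

from ehreval import (
    AnnotationSet,
    SliceRequest,
    SyntheticConfig,
    compute_sample_size,
)


# ---------------------------------------------------------------------------
# independent oracles


def cp_bisect(r: int, n: int, alpha: float = 0.05, tol: float = 1e-12):
    """Clopper-Pearson bounds by bisection on exact binomial tail sums.

    Lower bound: the p with P[X >= r | n, p] = alpha/2 (0 when r = 0).
    Upper bound: the p with P[X <= r | n, p] = alpha/2 (1 when r = n).
    Independent of the package's Beta/F quantile route.
    """
    half = alpha / 2.0

    def solve(tail, target):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2.0
            if tail(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    lower = 0.0 if r == 0 else solve(lambda p: binom.sf(r - 1, n, p), half)
    upper = 1.0 if r == n else solve(lambda p: 1.0 - binom.cdf(r, n, p), 1.0 - half)
    return lower, upper


def exhaustive_min_n(p: float, half_width: float, alpha: float, n_max: int):
    """Smallest n with CP width <= 2*half_width, by direct scan using the
    bisection oracle; returns None if no n <= n_max qualifies."""
    for n in range(1, n_max + 1):
        r = int(math.floor(p * n + 0.5))
        lo, hi = cp_bisect(r, n, alpha, tol=1e-10)
        if hi - lo <= 2 * half_width:
            return n
    return None


@pytest.fixture(scope="session")
def bisection_oracle():
    return cp_bisect


@pytest.fixture(scope="session")
def asthma_request():
    """The multi-hospital sizing request of the worked example."""
    return SliceRequest(
        expected_precision=0.85,
        expected_recall=0.80,
        frequency=0.485,
        confidence_level=0.95,
        half_width=0.05,
        frequency_mode="external",
        n_hospitals=6,
    )


@pytest.fixture(scope="session")
def asthma_result(asthma_request):
    return compute_sample_size(asthma_request)


# ---------------------------------------------------------------------------
# small annotation grids


def make_annotation_set(annotator_id, doc_ids, variables, present_cells):
    """Complete grid with 'present' exactly at the given (doc, var) cells."""
    labels = {
        (d, v): (d, v) in set(present_cells)
        for d in doc_ids
        for v in variables
    }
    return AnnotationSet(annotator_id=annotator_id, labels=labels)


@pytest.fixture
def grid_factory():
    return make_annotation_set


@pytest.fixture
def small_synthetic_config():
    return SyntheticConfig(
        n_hospitals=2,
        docs_per_hospital=150,
        primary_prevalence=0.485,
        secondary_prevalences={"secondary_a": 0.3},
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
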