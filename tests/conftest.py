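"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings
    settings.register_profile(
        "suite",
        deadline=None,
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover - hypothesis is in the test extra
    pass

from metabodx import CohortConfig, build_peak_library, simulate_cohort


@pytest.fixture(scope="session")
def library():
    return build_peak_library()


@pytest.fixture(scope="session")
def small_cohort(library):
    """A quick balanced cohort for plumbing tests (not for power checks)."""
    cfg = CohortConfig(n_samples=16, prevalence=0.5, points_per_spectrum=4096,
                       seed=11)
    return simulate_cohort(cfg, library)


def fine_axis(points=100001, lo=0.0, hi=10.0):
    return np.linspace(lo, hi, points)


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementations they check)


def auc_by_pair_counting(scores, labels01):
    """Mann-Whitney AUC: concordant pairs + half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01).astype(int)
    pos = scores[labels01 == 1]
    neg = scores[labels01 == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def _log_hypergeom_pmf(a, row1, col1, n):
    """log P(A = a) for a 2x2 table with margins (row1, col1, total n)."""
    return (math.lgamma(col1 + 1) - math.lgamma(a + 1) - math.lgamma(col1 - a + 1)
            + math.lgamma(n - col1 + 1) - math.lgamma(row1 - a + 1)
            - math.lgamma(n - col1 - row1 + a + 1)
            - (math.lgamma(n + 1) - math.lgamma(row1 + 1) - math.lgamma(n - row1 + 1)))


def fisher_bruteforce(a, b, c, d):
    """One-sided (greater) and point-probability two-sided Fisher p-values
    by explicit enumeration of all tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    a_min = max(0, row1 + col1 - n)
    a_max = min(row1, col1)
    pmf = {}
    for x in range(a_min, a_max + 1):
        pmf[x] = math.exp(_log_hypergeom_pmf(x, row1, col1, n))
    p_obs = pmf[a]
    p_greater = sum(p for x, p in pmf.items() if x >= a)
    p_two = sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-12))
    return min(p_greater, 1.0), min(p_two, 1.0)


def topleft_bruteforce(roc):
    """Closest-to-top-left threshold by exhaustive enumeration with the
    same tie rules (higher specificity, then higher threshold)."""
    best = None
    for thr, tpr, fpr in zip(roc.thresholds, roc.tpr, roc.fpr):
        key = ((1 - tpr) ** 2 + fpr ** 2, fpr, -thr)
        if best is None or key < best[0]:
            best = (key, thr)
    return best[1]
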