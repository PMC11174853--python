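import numpy as np
import pytest

from nbshift.count_model import ThetaTrend


@pytest.fixture(scope="session")
def trend() -> ThetaTrend:
    """An analytic theta trend, theta(mu) = exp(0.5 + 0.4 log mu)."""
    return ThetaTrend(intercept=0.5, slope=0.4, mu_min=8.0, mu_max=2000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240530)


def brute_force_shift(a, b) -> float:
    """Independent oracle: double loop over pooled distinct values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = 0.0
    for x in sorted(set(a.tolist()) | set(b.tolist())):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        total += fa - fb
    return total


def brute_force_depth(intervals) -> int:
    """Independent oracle: per-position coverage counter."""
    iv = list(intervals)
    if not iv:
        return 0
    positions = range(
        int(min(s for s, _ in iv)), int(max(e for _, e in iv))
    )
    return max(sum(1 for s, e in iv if s <= pos < e) for pos in positions)


def hypergeom_tail(a, b, c, d, tail) -> float:
    """Independent oracle: direct hypergeometric summation for the 2x2
    table [[a, b], [c, d]] with fixed margins."""
    from math import comb

    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    if tail == "greater":
        ks = range(a, hi + 1)
    else:
        ks = range(lo, a + 1)
    return sum(comb(row1, k) * comb(n - row1, col1 - k) for k in ks) / denom
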