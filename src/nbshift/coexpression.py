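"""Gene-pair correlation from simulated NB2 counts.

Correlation between diurnal profiles is measured on counts re-simulated from
the estimated means and the dispersion trend: 30 draws per time point, log2
with the >=8 floor.  Each gene gets four independent simulated vectors; the
pair correlation aggregates the Pearson coefficients of the 16 cross
pairings.  The geometric mean of signed coefficients is undefined for mixed
signs, so the aggregate is the signed geometric mean of absolute values when
all pairings agree in sign and the arithmetic mean otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .count_model import ThetaTrend
from .shiftstats import floor_log2

DRAWS_PER_POINT = 30
N_SIMULATIONS = 4
COEXPRESSION_THRESHOLD = 0.7
COREGULATION_THRESHOLD = 0.5

__all__ = [
    "CorrelationResult",
    "simulate_profile",
    "pair_correlation",
    "timepoint_correlation",
    "correlation_pvalue",
    "coexpression_call",
    "preservation_and_coregulation",
]


@dataclass
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float
    basis: str  # "diurnal", "per-timepoint" or "cross-line"
    n_effective: int
    mixed_sign: bool = False


def _nb_draws(means, thetas, size, rng) -> np.ndarray:
    means = np.asarray(means, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    p = thetas / (thetas + means)
    return rng.negative_binomial(thetas, p, size=size)


def simulate_profile(
    means,
    trend: ThetaTrend,
    draws_per_point: int = DRAWS_PER_POINT,
    seed=None,
    rng=None,
) -> np.ndarray:
    """Simulated log2 expression vector: ``draws_per_point`` NB2 draws per
    time-point mean, concatenated in time-point order, floored at 8."""
    rng = np.random.default_rng(seed) if rng is None else rng
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("means must be positive")
    thetas = np.atleast_1d(trend.predict_theta(means))
    counts = _nb_draws(means, thetas, (draws_per_point, means.size), rng)
    return floor_log2(counts.T.ravel())


def _aggregate_correlations(rs: list[float]) -> tuple[float, bool]:
    arr = np.asarray(rs, dtype=float)
    if arr.size == 0:
        raise ValueError("no defined correlations to aggregate")
    if np.all(arr > 0) or np.all(arr < 0):
        sign = 1.0 if arr[0] > 0 else -1.0
        return float(sign * np.exp(np.mean(np.log(np.abs(arr))))), False
    return float(np.mean(arr)), True


def _cross_correlations(sims_a, sims_b) -> list[float]:
    rs = []
    for va in sims_a:
        for vb in sims_b:
            if np.std(va) == 0 or np.std(vb) == 0:
                continue
            rs.append(float(np.corrcoef(va, vb)[0, 1]))
    return rs


def pair_correlation(
    means_a,
    means_b,
    trend: ThetaTrend,
    seed=None,
    rng=None,
    draws_per_point: int = DRAWS_PER_POINT,
    n_simulations: int = N_SIMULATIONS,
    gene_a: str = "a",
    gene_b: str = "b",
    basis: str = "diurnal",
) -> CorrelationResult:
    """Aggregate Pearson correlation of two genes' simulated diurnal profiles.

    Four independent simulations per gene; the 16 cross-pairing coefficients
    are aggregated sign-aware (see module docstring).  Pairings with a
    zero-variance vector are dropped; if all are dropped this raises.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    sims_a = [
        simulate_profile(means_a, trend, draws_per_point, rng=rng)
        for _ in range(n_simulations)
    ]
    sims_b = [
        simulate_profile(means_b, trend, draws_per_point, rng=rng)
        for _ in range(n_simulations)
    ]
    rs = _cross_correlations(sims_a, sims_b)
    if not rs:
        raise ValueError("all simulated pairings had zero variance")
    r, mixed = _aggregate_correlations(rs)
    n_eff = draws_per_point * len(np.atleast_1d(np.asarray(means_a)))
    return CorrelationResult(gene_a, gene_b, r, basis, n_eff, mixed)


def timepoint_correlation(
    means_a,
    means_b,
    trend: ThetaTrend,
    timepoint_index: int,
    seed=None,
    rng=None,
    draws_per_point: int = DRAWS_PER_POINT,
    n_simulations: int = N_SIMULATIONS,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CorrelationResult:
    """Pair correlation restricted to a single time point's 30-draw blocks.

    Shares the simulation and 16-combination aggregation path of
    :func:`pair_correlation`, using the partial mean of the tested point.
    """
    t = timepoint_index
    mean_a = [float(np.asarray(means_a, dtype=float)[t])]
    mean_b = [float(np.asarray(means_b, dtype=float)[t])]
    res = pair_correlation(
        mean_a,
        mean_b,
        trend,
        seed=seed,
        rng=rng,
        draws_per_point=draws_per_point,
        n_simulations=n_simulations,
        gene_a=gene_a,
        gene_b=gene_b,
        basis="per-timepoint",
    )
    return res


def correlation_pvalue(r: float, n: int) -> float:
    """Asymptotic two-sided p-value for a Pearson correlation (t-transform
    with n - 2 degrees of freedom)."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def coexpression_call(r: float, threshold: float = COEXPRESSION_THRESHOLD) -> bool:
    """A pair is coexpressed when r reaches the shared-variance threshold
    (r >= 0.7, i.e. about half of common variance)."""
    return bool(r >= threshold)


def preservation_and_coregulation(
    coexpressed_a: set,
    correlations_b: dict,
    cross_line_r: dict,
    threshold: float = COEXPRESSION_THRESHOLD,
    coregulation_threshold: float = COREGULATION_THRESHOLD,
) -> tuple[float, set, set]:
    """Cross-line preservation of coexpression and coregulated pairs.

    ``coexpressed_a``: pairs (frozenset or tuple) coexpressed in line A.
    ``correlations_b``: pair -> r in line B.
    ``cross_line_r``: gene -> cross-line diurnal-pattern correlation.
    Returns (preservation rate, preserved pairs, coregulated pairs), where a
    preserved pair is coregulated when both members' diurnal patterns
    transformed drastically between lines (cross-line r < 0.5).
    """
    if not coexpressed_a:
        return float("nan"), set(), set()
    preserved = {
        pair
        for pair in coexpressed_a
        if coexpression_call(correlations_b[pair], threshold)
    }
    rate = len(preserved) / len(coexpressed_a)
    coregulated = {
        pair
        for pair in preserved
        if all(cross_line_r[g] < coregulation_threshold for g in pair)
    }
    return rate, preserved, coregulated
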