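"""NB2 count-model machinery.

Counts are modeled as NB2(mu, theta) with variance mu + mu**2/theta.  Because
per-gene dispersion cannot be estimated from a handful of replicates, genes of
similar rounded mean abundance are pooled into bins, theta is estimated by
maximum likelihood per bin, and a gamma log-linear regression of the binned
theta estimates on log mean count yields a smooth mean->theta trend.  Per-gene
means are then re-estimated by maximizing the smallest two-sided tail
probability of the observed replicates under the trend, with low-probability
replicates trimmed as outliers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

THETA_CAP = 1.0e6
THETA_FLOOR = 1.0e-3

__all__ = [
    "THETA_CAP",
    "NBModel",
    "Bin",
    "ThetaTrend",
    "GeneEstimate",
    "nb2_variance",
    "pool_bins",
    "fit_theta_mle",
    "fit_theta_trend",
    "estimate_mean_trimmed",
    "estimate_means_table",
]


def nb2_variance(mu: float, theta: float) -> float:
    """Quadratic mean-variance relationship ``mu + mu**2 / theta``."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if np.any(np.asarray(mu) < 0):
        raise ValueError(f"mu must be nonnegative, got {mu}")
    return mu + mu**2 / theta


@dataclass(frozen=True)
class NBModel:
    """A single NB2 law with mean ``mu`` and shape ``theta``."""

    mu: float
    theta: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def variance(self) -> float:
        return nb2_variance(self.mu, self.theta)

    def dist(self) -> stats.rv_discrete:
        return stats.nbinom(self.theta, self.theta / (self.theta + self.mu))


@dataclass
class Bin:
    """A pool of counts from units with the same (or merged) rounded mean."""

    label: int
    n_members: int
    counts: np.ndarray
    theta: float | None = None

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))


def pool_bins(
    means: np.ndarray,
    counts: list[np.ndarray],
    min_mean: int = 8,
    min_bin_size: int = 30,
) -> list[Bin]:
    """Pool replicate counts of units with similar rounded means into bins.

    ``means`` are method-of-moments means per unit (one unit = one gene in one
    sample group); units with rounded mean below ``min_mean`` are excluded.
    Underpopulated bins are merged upward (toward larger means); a trailing
    underpopulated bin is merged into the previous one.
    """
    means = np.asarray(means, dtype=float)
    if len(means) != len(counts):
        raise ValueError("means and counts must have the same length")
    rounded = np.round(means).astype(int)
    keep = rounded >= min_mean
    if not np.any(keep):
        raise ValueError(
            f"no units with rounded mean >= {min_mean}; provide more genes"
        )

    groups: dict[int, list[np.ndarray]] = {}
    for r, c in zip(rounded[keep], (counts[i] for i in np.flatnonzero(keep))):
        groups.setdefault(int(r), []).append(np.asarray(c))

    bins: list[Bin] = []
    carry: list[np.ndarray] = []
    carry_n = 0
    for label in sorted(groups):
        carry.extend(groups[label])
        carry_n += len(groups[label])
        if carry_n >= min_bin_size:
            bins.append(Bin(label, carry_n, np.concatenate(carry)))
            carry, carry_n = [], 0
    if carry_n:
        if bins:
            last = bins[-1]
            bins[-1] = Bin(
                last.label,
                last.n_members + carry_n,
                np.concatenate([last.counts] + carry),
            )
        else:
            raise ValueError(
                f"no bin reaches {min_bin_size} members; provide more genes"
            )
    return bins


def _nb_negloglik(log_theta: float, counts: np.ndarray, mu: float) -> float:
    theta = math.exp(log_theta)
    p = theta / (theta + mu)
    return -float(np.sum(stats.nbinom.logpmf(counts, theta, p)))


def fit_theta_mle(bin_counts: np.ndarray, cap: float = THETA_CAP) -> float:
    """Profile-likelihood MLE of NB2 theta for a pool of counts.

    The mean MLE of an NB2 with free mean is the sample mean, so theta is
    estimated by one-dimensional optimization of the profile likelihood.
    Under-dispersed pools (sample variance <= mean) return ``cap``.
    """
    counts = np.asarray(bin_counts)
    mu = float(np.mean(counts))
    if mu <= 0:
        raise ValueError("cannot fit theta to all-zero counts")
    var = float(np.var(counts, ddof=1)) if len(counts) > 1 else 0.0
    if var <= mu:
        return cap
    # method-of-moments start: var = mu + mu^2/theta
    theta0 = mu**2 / (var - mu)
    lo, hi = math.log(THETA_FLOOR), math.log(cap)
    res = optimize.minimize_scalar(
        _nb_negloglik,
        bounds=(lo, hi),
        args=(counts, mu),
        method="bounded",
        options={"xatol": 1e-8},
    )
    theta = math.exp(res.x)
    # guard against a flat likelihood pinning at the lower bound
    if not np.isfinite(theta) or theta <= THETA_FLOOR * 1.01:
        theta = min(max(theta0, THETA_FLOOR), cap)
    return float(min(theta, cap))


@dataclass
class ThetaTrend:
    """Fitted mean->theta function: ``theta(mu) = exp(a + b*log(mu))``.

    Predictions outside ``[mu_min, mu_max]`` are clamped to the boundary,
    keeping the trend defined (and positive) everywhere.
    """

    intercept: float
    slope: float
    mu_min: float
    mu_max: float
    bins: list[Bin] = field(default_factory=list)
    cap: float = THETA_CAP

    def predict_theta(self, mu):
        mu_arr = np.clip(np.asarray(mu, dtype=float), self.mu_min, self.mu_max)
        theta = np.exp(self.intercept + self.slope * np.log(mu_arr))
        theta = np.clip(theta, THETA_FLOOR, self.cap)
        if np.isscalar(mu) or np.ndim(mu) == 0:
            return float(theta)
        return theta

    def variance(self, mu):
        return mu + np.asarray(mu) ** 2 / self.predict_theta(mu)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "slope": self.slope,
                "mu_min": self.mu_min,
                "mu_max": self.mu_max,
                "bins": [
                    {
                        "label": b.label,
                        "n_members": b.n_members,
                        "mean_count": b.mean_count,
                        "theta": b.theta,
                    }
                    for b in self.bins
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ThetaTrend":
        obj = json.loads(text)
        return cls(
            intercept=obj["intercept"],
            slope=obj["slope"],
            mu_min=obj["mu_min"],
            mu_max=obj["mu_max"],
        )


def fit_theta_trend(bins: list[Bin], cap: float = THETA_CAP) -> ThetaTrend:
    """Gamma log-linear regression of per-bin theta MLEs on log mean count."""
    if len(bins) < 2:
        raise ValueError("need at least 2 bins to fit a theta trend")
    for b in bins:
        if b.theta is None:
            b.theta = fit_theta_mle(b.counts, cap=cap)
    means = np.array([b.mean_count for b in bins])
    thetas = np.array([b.theta for b in bins])
    X = sm.add_constant(np.log(means))
    if np.allclose(thetas, thetas[0]):
        # degenerate flat trend; the GLM is ill-posed but the answer is exact
        return ThetaTrend(
            intercept=float(np.log(thetas[0])),
            slope=0.0,
            mu_min=float(means.min()),
            mu_max=float(means.max()),
            bins=bins,
            cap=cap,
        )
    model = sm.GLM(thetas, X, family=sm.families.Gamma(sm.families.links.Log()))
    fit = model.fit()
    return ThetaTrend(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        mu_min=float(means.min()),
        mu_max=float(means.max()),
        bins=bins,
        cap=cap,
    )


@dataclass
class GeneEstimate:
    """Outlier-trimmed mean estimate for one gene in one sample group."""

    gene: str
    sample: str
    mean: float
    retained: int
    outlier_indices: list[int]
    excluded: bool

    @property
    def df(self) -> int:
        """Degrees of freedom carried by the replicated mean values."""
        return self.retained


def _tail_probability(counts: np.ndarray, mu, trend: ThetaTrend) -> np.ndarray:
    """Two-sided tail mass min(CDF(x), 1 - CDF(x-1)) under NB2(mu, theta(mu)).

    ``mu`` may be a vector of candidate means; the result is then shaped
    (len(mu), len(counts)).
    """
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    theta = np.atleast_1d(trend.predict_theta(mu_arr))
    p = theta / (theta + mu_arr)
    x = np.asarray(counts)[None, :]
    lower = stats.nbinom.cdf(x, theta[:, None], p[:, None])
    upper = stats.nbinom.sf(x - 1, theta[:, None], p[:, None])
    out = np.minimum(lower, upper)
    if np.isscalar(mu) or np.ndim(mu) == 0:
        return out[0]
    return out


def _maximize_min_tail(
    counts: np.ndarray, trend: ThetaTrend, rel_tol: float = 1e-4
) -> tuple[float, np.ndarray]:
    """Grid search (coarse then refined) for the mean maximizing the smallest
    two-sided tail probability of the counts."""
    lo = max(float(np.min(counts)), 1e-3)
    hi = max(float(np.max(counts)), lo)
    if hi <= lo * (1 + 1e-12):
        mu = hi
        return mu, _tail_probability(counts, mu, trend)
    n_grid = 129
    grid = np.linspace(lo, hi, n_grid)
    for _ in range(3):  # three refinement passes: span shrinks ~64x per pass
        obj = _tail_probability(counts, grid, trend).min(axis=1)
        best = int(np.argmax(obj))
        lo_i = grid[max(best - 1, 0)]
        hi_i = grid[min(best + 1, len(grid) - 1)]
        if (hi_i - lo_i) / max(grid[best], 1e-12) < rel_tol:
            break
        grid = np.linspace(lo_i, hi_i, n_grid)
    mu = float(grid[best])
    return mu, _tail_probability(counts, mu, trend)


def estimate_mean_trimmed(
    replicate_counts,
    trend: ThetaTrend,
    alpha: float = 0.05,
    gene: str = "",
    sample: str = "",
) -> GeneEstimate:
    """Iterative outlier-trimmed mean of replicate counts under the trend.

    The mean maximizes the smallest two-sided tail probability of the retained
    counts in NB2(mu, theta(mu)).  A count whose tail probability at the
    maximizing mean falls below ``alpha`` is an outlier: the worst one is
    removed and the mean re-estimated, as long as at least two counts remain.
    Needing more removals than ``n_replicates - 2`` marks the gene excluded
    (with three replicates only a single outlier can ever be trimmed).
    """
    counts = np.asarray(replicate_counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need at least 2 replicate counts")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")

    active = list(range(len(counts)))
    outliers: list[int] = []
    excluded = False
    while True:
        sub = counts[active]
        mu, tails = _maximize_min_tail(sub, trend)
        bad = tails < alpha
        if not bad.any():
            break
        if len(active) - 1 < 2:
            excluded = True
            break
        # one-step lookahead: among the flagged counts, drop the one whose
        # removal leaves the remaining counts most probable (the compromise
        # mean can make the tail probabilities of two extremes nearly equal,
        # so the smallest tail alone is a fragile criterion)
        best_obj, worst = -1.0, -1
        for cand in np.flatnonzero(bad):
            rest = np.delete(sub, cand)
            _, rest_tails = _maximize_min_tail(rest, trend)
            obj = float(rest_tails.min())
            if obj > best_obj:
                best_obj, worst = obj, int(cand)
        outliers.append(active.pop(worst))
    return GeneEstimate(
        gene=gene,
        sample=sample,
        mean=mu,
        retained=len(active),
        outlier_indices=sorted(outliers),
        excluded=excluded,
    )


def estimate_means_table(
    counts: np.ndarray,
    trend: ThetaTrend,
    alpha: float = 0.05,
    genes=None,
    samples=None,
):
    """Trimmed estimates for a (gene x group x replicate) count array.

    Returns a pandas DataFrame with one row per (gene, group).
    """
    import pandas as pd

    counts = np.asarray(counts)
    n_genes, n_groups, _ = counts.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = (
        list(samples) if samples is not None else [f"s{j}" for j in range(n_groups)]
    )
    rows = []
    for i in range(n_genes):
        for j in range(n_groups):
            est = estimate_mean_trimmed(
                counts[i, j], trend, alpha=alpha, gene=genes[i], sample=samples[j]
            )
            rows.append(
                {
                    "gene": est.gene,
                    "sample": est.sample,
                    "mean": est.mean,
                    "retained": est.retained,
                    "n_outliers": len(est.outlier_indices),
                    "excluded": est.excluded,
                }
            )
    return pd.DataFrame(rows)
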