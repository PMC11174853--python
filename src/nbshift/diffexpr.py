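"""NB-GLM Wald differential expression and time-point association.

The Wald test regresses replicated trimmed mean values on a two-level group
indicator under a log-link NB2 model with theta fixed from the mean->theta
trend (no extra scale parameter).  With a saturated two-group design the MLE
coefficient is the log ratio of group means and its variance follows in
closed form from the expected Fisher information, so the test is computed
analytically rather than through an iterative GLM fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .count_model import GeneEstimate, ThetaTrend, nb2_variance

ABUNDANCE_FLOOR = 8.0
FC_FLOOR = 0.9
ALPHA = 0.05

__all__ = [
    "DEResult",
    "TimepointCluster",
    "wald_test",
    "bh_adjust",
    "call_degs",
    "timepoint_association",
    "classify_activity_change",
]


@dataclass
class DEResult:
    gene: str
    timepoint: str
    log2fc: float
    p: float
    p_adj: float
    status: str  # UP, DOWN or NONE
    passed_abundance_filter: bool
    passed_fc_filter: bool


@dataclass(frozen=True)
class TimepointCluster:
    gene: str
    timepoint: str
    direction: str  # "overexpressed" or "underexpressed"


def _wald_floored(
    mean_a: float,
    n_a: int,
    mean_b: float,
    n_b: int,
    theta: float,
    floor: float = ABUNDANCE_FLOOR,
) -> tuple[float, float]:
    """(log2fc, two-tailed p) for floored group means with fixed theta.

    Means below ``floor`` are raised to it before both the fold change and the
    test, which guards genes expressed in only one line against fold-change
    overestimation; ties at the floor give log2fc = 0 and p = 1.
    """
    fa = max(float(mean_a), floor)
    fb = max(float(mean_b), floor)
    log2fc = math.log2(fb / fa)
    if fa == fb:
        return log2fc, 1.0
    se2 = nb2_variance(fa, theta) / (n_a * fa**2) + nb2_variance(fb, theta) / (
        n_b * fb**2
    )
    z = math.log(fb / fa) / math.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return log2fc, float(p)


def wald_test(
    estimate_a: GeneEstimate,
    estimate_b: GeneEstimate,
    theta: float,
    floor: float = ABUNDANCE_FLOOR,
) -> tuple[float, float] | None:
    """Wald test of zero log fold change between two trimmed estimates.

    ``theta`` should be the trend prediction at the average of the tested
    means.  Degrees of freedom come from the retained-replicate counts of the
    estimates.  Excluded estimates yield no result (``None``).
    """
    if estimate_a.excluded or estimate_b.excluded:
        return None
    return _wald_floored(
        estimate_a.mean,
        estimate_a.retained,
        estimate_b.mean,
        estimate_b.retained,
        theta,
        floor=floor,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    results: pd.DataFrame,
    abundance_floor: float = ABUNDANCE_FLOOR,
    fc_floor: float = FC_FLOOR,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Apply BH correction and the abundance / fold-change filters.

    ``results`` needs columns gene, timepoint, mean_a, mean_b, log2fc, p.
    BH families are per time point.  Status is UP when b is over a
    (log2fc >= fc_floor), DOWN when log2fc <= -fc_floor, both subject to
    adjusted p < alpha and max(mean) >= abundance_floor.
    """
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby("timepoint").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["passed_abundance_filter"] = (
        np.maximum(out["mean_a"], out["mean_b"]) >= abundance_floor
    )
    out["passed_fc_filter"] = out["log2fc"].abs() >= fc_floor
    significant = (
        (out["p_adj"] < alpha)
        & out["passed_abundance_filter"]
        & out["passed_fc_filter"]
    )
    out["status"] = "NONE"
    out.loc[significant & (out["log2fc"] > 0), "status"] = "UP"
    out.loc[significant & (out["log2fc"] < 0), "status"] = "DOWN"
    return out


def timepoint_association(
    means: np.ndarray,
    retained: np.ndarray,
    trend: ThetaTrend,
    gene: str = "",
    timepoints=None,
    fold: float = 2.0,
    alpha: float = ALPHA,
    floor: float = ABUNDANCE_FLOOR,
) -> list[TimepointCluster]:
    """Cluster a gene by a sharp expression change at one time point.

    ``means``/``retained`` hold the trimmed estimate and its retained
    replicates at each time point.  The gene joins the cluster at point t iff
    its (floored) mean differs at least ``fold``-fold from every other point
    in a consistent direction and all three BH-adjusted Wald p-values are
    below ``alpha``.  Theta is the trend value at the mean of the tested
    means across all points.
    """
    m = np.maximum(np.asarray(means, dtype=float), floor)
    n = np.asarray(retained, dtype=int)
    n_tp = len(m)
    if timepoints is None:
        timepoints = [str(i) for i in range(n_tp)]
    theta = trend.predict_theta(float(np.mean(m)))
    clusters: list[TimepointCluster] = []
    for t in range(n_tp):
        others = [k for k in range(n_tp) if k != t]
        if all(m[t] >= fold * m[k] for k in others):
            direction = "overexpressed"
        elif all(m[t] <= m[k] / fold for k in others):
            direction = "underexpressed"
        else:
            continue
        ps = [
            _wald_floored(m[k], n[k], m[t], n[t], theta, floor=floor)[1]
            for k in others
        ]
        if np.all(bh_adjust(ps) < alpha):
            clusters.append(TimepointCluster(gene, timepoints[t], direction))
    return clusters


def classify_activity_change(
    cs_profile,
    ds_profile,
    timepoint_index: int,
) -> str:
    """Classify one differential-expression event by diurnal-activity change.

    Profiles are log-scale expression across the time points (floors already
    applied).  Relative to each line's own mean diurnal expression:
    ``inversion`` when the two lines sit on strictly opposite sides,
    ``enhancement`` when the substituted line sits on the same side but
    farther out, ``weakening`` otherwise (including ties on the mean).
    """
    cs = np.asarray(cs_profile, dtype=float)
    ds = np.asarray(ds_profile, dtype=float)
    dev_cs = cs[timepoint_index] - cs.mean()
    dev_ds = ds[timepoint_index] - ds.mean()
    if dev_cs * dev_ds < 0:
        return "inversion"
    if abs(dev_ds) > abs(dev_cs):
        return "enhancement"
    return "weakening"
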