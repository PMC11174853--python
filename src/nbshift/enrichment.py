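"""Fisher's exact over-/under-representation for annotated gene sets.

Directional (one-tailed) tests per the reporting convention: the ``greater``
tail tests over-representation of a term among the hits, ``less`` tests
under-representation.  p-values are BH-adjusted within each (hit-set,
term-class) family and filtered at the adjusted cutoff.  Paralog statistics
are adjusted by restricting to genes with at least one paralog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "AnnotationSet",
    "ParalogStats",
    "fisher_overrep",
    "enrich_all",
    "paralog_enrichment",
]


@dataclass
class AnnotationSet:
    term: str
    term_class: str  # "BP", "pathway" or "cluster-pair"
    members: set = field(default_factory=set)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = set(self.members)
        self.universe = set(self.universe)
        if not self.members <= self.universe:
            raise ValueError(
                f"term {self.term!r}: members must be a subset of the universe"
            )


def fisher_overrep(
    hits: set, term: AnnotationSet, tail: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test of term representation among the hit genes.

    Returns (odds ratio, one-tailed p).  The 2x2 table is built inside the
    term's universe; hits outside the universe are ignored.
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    universe = term.universe
    if not universe:
        raise ValueError("empty universe")
    hits_in = set(hits) & universe
    a = len(hits_in & term.members)
    b = len(hits_in) - a
    c = len(term.members) - a
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=tail)
    return float(odds), float(p)


def enrich_all(
    hit_sets: dict[str, set],
    annotation_sets: list[AnnotationSet],
    alpha: float = 0.05,
    tail: str = "greater",
) -> pd.DataFrame:
    """Test every (hit set, term) combination, BH-adjust per family, filter.

    BH families are one per (hit set, term class); rows with adjusted
    p >= ``alpha`` are dropped.
    """
    rows = []
    for hit_name, hits in hit_sets.items():
        for term in annotation_sets:
            hits_in = set(hits) & term.universe
            if not hits_in:
                continue
            odds, p = fisher_overrep(hits_in, term, tail=tail)
            expected = len(hits_in) * len(term.members) / len(term.universe)
            rows.append(
                {
                    "hit_set": hit_name,
                    "term": term.term,
                    "term_class": term.term_class,
                    "n_hits": len(hits_in & term.members),
                    "expected": expected,
                    "odds": odds,
                    "p": p,
                }
            )
    columns = [
        "hit_set", "term", "term_class", "n_hits", "expected", "odds", "p",
        "p_adj",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for _, idx in table.groupby(["hit_set", "term_class"]).groups.items():
        table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    return table.loc[table["p_adj"] < alpha, columns].reset_index(drop=True)


@dataclass
class ParalogStats:
    """Paralog abundance of a gene set, with the >=1-paralog adjustment."""

    n_genes: int
    n_with_paralog: int
    paralogs_per_gene: float
    paralogs_per_gene_adjusted: float


def paralog_enrichment(gene_set: set, clusters: dict) -> ParalogStats:
    """Mean paralog partners per gene of a set under a cluster map.

    ``clusters`` maps gene -> paralog cluster id; a gene in a cluster of size
    k has k - 1 partners, unmapped genes have none.  The adjusted mean
    restricts to set members with at least one paralog (in a genome of pure
    homoeologous triplets both means are exactly 2).
    """
    genes = list(gene_set)
    sizes: dict = {}
    for cid in clusters.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    partners = np.array(
        [sizes[clusters[g]] - 1 if g in clusters else 0 for g in genes],
        dtype=float,
    )
    with_paralog = partners >= 1
    n_with = int(with_paralog.sum())
    mean_all = float(partners.mean()) if genes else float("nan")
    mean_adj = float(partners[with_paralog].mean()) if n_with else float("nan")
    return ParalogStats(
        n_genes=len(genes),
        n_with_paralog=n_with,
        paralogs_per_gene=mean_all,
        paralogs_per_gene_adjusted=mean_adj,
    )
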