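"""Synthetic datasets with the statistical structure the pipeline assumes.

Counts are NB2 draws around per-gene diurnal mean profiles with a log-linear
mean->theta dispersion trend, for two genotypes x four time points x
replicates.  The generator can inject per-time-point differential expression
with known truth labels, replicate outliers, a global per-time-point genotype
shift, a stably expressed housekeeping gene, and annotation maps
(chromosomes, BP terms, pathways, paralog clusters — mostly homoeologous
triplets).  Everything is driven by one seed: identical configs and seeds
give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_LINES = ("CS", "DS")
DEFAULT_TIMEPOINTS = ("0h", "3h", "9h", "16h")
CHROMOSOMES = tuple(f"{i}{g}" for i in range(1, 8) for g in "ABD")

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_dataset",
    "make_read_alignments",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    lines: tuple = DEFAULT_LINES
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    # theta(mu) = exp(a + b * log(mu)): dispersion grows with the mean
    theta_trend_params: tuple = (0.5, 0.4)
    deg_fraction: float = 0.0
    deg_effect_log2fc: float = 2.0
    all_timepoint_deg_fraction: float = 0.0
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 20.0
    paralog_cluster_size_distribution: dict = field(
        default_factory=lambda: {3: 1.0}
    )
    housekeeping_mean: float = 200.0
    n_bp_terms: int = 0
    n_pathway_terms: int = 0
    mean_log2_range: tuple = (3.0, 9.0)
    diurnal_amplitude_sd: float = 0.5
    # optional per-time-point log2 shift applied to the second line's means
    line_shift_log2fc: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if len(self.lines) != 2:
            raise ValueError("exactly two genotype lines are supported")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if self.outlier_multiplier <= 1.0:
            raise ValueError("outlier_multiplier must exceed 1")
        if self.deg_effect_log2fc <= 0:
            raise ValueError("deg_effect_log2fc must be positive")
        if self.housekeeping_mean <= 0:
            raise ValueError("housekeeping_mean must be positive")
        probs = np.array(list(self.paralog_cluster_size_distribution.values()))
        if len(probs) == 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("paralog cluster size probabilities must sum to 1")
        if self.line_shift_log2fc is not None and len(
            self.line_shift_log2fc
        ) != len(self.timepoints):
            raise ValueError("line_shift_log2fc needs one value per time point")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list
    counts: np.ndarray  # (gene, line, timepoint, replicate) integers
    true_means: np.ndarray  # (gene, line, timepoint)
    true_theta: np.ndarray  # (gene, line, timepoint)
    deg_truth: np.ndarray  # (gene, timepoint) of {"UP","DOWN","NONE"}
    outlier_truth: np.ndarray  # boolean, same shape as counts
    chromosome: dict
    bp_terms: dict
    pathway_terms: dict
    paralog_cluster: dict
    housekeeping_gene_id: str = "gene0000"

    @property
    def sample_names(self) -> list:
        cfg = self.config
        return [
            f"{line}_{tp}_rep{k + 1}"
            for line in cfg.lines
            for tp in cfg.timepoints
            for k in range(cfg.n_replicates)
        ]

    def sample_metadata(self) -> pd.DataFrame:
        cfg = self.config
        rows = [
            {"line": line, "timepoint": tp, "replicate": k + 1}
            for line in cfg.lines
            for tp in cfg.timepoints
            for k in range(cfg.n_replicates)
        ]
        return pd.DataFrame(rows, index=self.sample_names)

    def count_table(self) -> pd.DataFrame:
        flat = self.counts.reshape(len(self.genes), -1)
        return pd.DataFrame(flat, index=self.genes, columns=self.sample_names)

    def write_tsvs(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table = self.count_table()
        table.index.name = "gene"
        table.to_csv(outdir / "counts.tsv", sep="\t")
        for name, mapping in [
            ("chromosome", self.chromosome),
            ("paralog_cluster", self.paralog_cluster),
        ]:
            pd.Series(mapping, name=name).rename_axis("gene").to_csv(
                outdir / f"{name}.tsv", sep="\t"
            )
        for name, mapping in [
            ("bp_terms", self.bp_terms),
            ("pathway_terms", self.pathway_terms),
        ]:
            rows = [
                {"gene": g, "term": t} for g, terms in mapping.items() for t in terms
            ]
            pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
                outdir / f"{name}.tsv", sep="\t", index=False
            )
        cfg = self.config
        truth = pd.DataFrame(
            self.deg_truth, index=self.genes, columns=list(cfg.timepoints)
        )
        truth.index.name = "gene"
        truth.to_csv(outdir / "deg_truth.tsv", sep="\t")


def _assign_clusters(config: SimulationConfig, genes, rng) -> dict:
    sizes = np.array(sorted(config.paralog_cluster_size_distribution))
    probs = np.array(
        [config.paralog_cluster_size_distribution[s] for s in sizes], dtype=float
    )
    clusters: dict = {}
    i, cid = 0, 0
    order = rng.permutation(len(genes))
    while i < len(genes):
        size = int(rng.choice(sizes, p=probs))
        size = min(size, len(genes) - i)
        if size >= 2:
            for j in range(size):
                clusters[genes[order[i + j]]] = f"cluster{cid:05d}"
            cid += 1
        i += size
    return clusters


def _assign_terms(n_terms: int, prefix: str, genes, rng) -> dict:
    terms = [f"{prefix}{i:03d}" for i in range(n_terms)]
    mapping: dict = {}
    if not terms:
        return mapping
    for g in genes:
        k = int(rng.integers(0, 3))  # 0-2 terms per gene
        if k:
            chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
            mapping[g] = {terms[c] for c in chosen}
    return mapping


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset from the configuration (deterministic
    for a fixed config and seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g = config.n_genes
    n_l, n_t, n_r = len(config.lines), len(config.timepoints), config.n_replicates
    genes = [f"gene{i:04d}" for i in range(n_g)]
    hk = genes[0]

    lo, hi = config.mean_log2_range
    base = 2.0 ** rng.uniform(lo, hi, size=n_g)
    profile = 2.0 ** rng.normal(0.0, config.diurnal_amplitude_sd, size=(n_g, n_t))
    means_line = base[:, None] * profile  # (gene, timepoint), shared by lines
    true_means = np.repeat(means_line[:, None, :], n_l, axis=1)

    # housekeeping gene: flat and identical everywhere
    true_means[0, :, :] = config.housekeeping_mean

    deg_truth = np.full((n_g, n_t), "NONE", dtype=object)
    n_deg = int(round(config.deg_fraction * (n_g - 1)))
    if n_deg:
        deg_genes = rng.choice(np.arange(1, n_g), size=n_deg, replace=False)
        effect = 2.0**config.deg_effect_log2fc
        for g in deg_genes:
            all_points = rng.random() < config.all_timepoint_deg_fraction
            points = (
                np.arange(n_t) if all_points else [int(rng.integers(0, n_t))]
            )
            sign = 1 if rng.random() < 0.5 else -1
            for t in points:
                true_means[g, 1, t] *= effect if sign > 0 else 1.0 / effect
                deg_truth[g, t] = "UP" if sign > 0 else "DOWN"

    if config.line_shift_log2fc is not None:
        shift = 2.0 ** np.asarray(config.line_shift_log2fc, dtype=float)
        true_means[1:, 1, :] *= shift[None, :]

    a, b = config.theta_trend_params
    true_theta = np.exp(a + b * np.log(true_means))

    p = true_theta / (true_theta + true_means)
    counts = rng.negative_binomial(
        true_theta[..., None], p[..., None], size=(n_g, n_l, n_t, n_r)
    )

    outlier_truth = np.zeros(counts.shape, dtype=bool)
    if config.outlier_fraction > 0:
        mask = rng.random(counts.shape) < config.outlier_fraction
        mask[0] = False  # keep the housekeeping gene clean
        counts = np.where(
            mask, np.round(counts * config.outlier_multiplier).astype(int), counts
        )
        outlier_truth = mask

    chromosome = {g: CHROMOSOMES[int(c)] for g, c in zip(
        genes, rng.integers(0, len(CHROMOSOMES), size=n_g)
    )}
    chromosome[hk] = "5A"  # the housekeeping gene sits outside the substituted 5B
    return SyntheticDataset(
        config=config,
        genes=genes,
        counts=counts.astype(np.int64),
        true_means=true_means,
        true_theta=true_theta,
        deg_truth=deg_truth,
        outlier_truth=outlier_truth,
        chromosome=chromosome,
        bp_terms=_assign_terms(config.n_bp_terms, "BP", genes, rng),
        pathway_terms=_assign_terms(config.n_pathway_terms, "path", genes, rng),
        paralog_cluster=_assign_clusters(config, genes, rng),
        housekeeping_gene_id=hk,
    )


def make_read_alignments(
    dataset: SyntheticDataset,
    read_length: int = 75,
    nonunique_fraction: float = 0.0,
    incomplete_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit alignment intervals whose greatest coverage depth equals the
    stored count for every (gene, sample).

    For a count c the emitted unique/complete intervals are staggered
    ``[i, i + read_length)`` for i < c, which stack to depth exactly c.
    Flagged (non-unique or incomplete) decoy intervals are added on top for
    configurable fractions of cells; the quantification filters must exclude
    them to reproduce the counts.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    rng = np.random.default_rng(dataset.config.seed if seed is None else seed)
    table = dataset.count_table()
    rows = []
    for gene in table.index:
        for sample in table.columns:
            c = int(table.loc[gene, sample])
            # staggering keeps intervals distinct but stacked to depth c;
            # it only works while the stagger stays within one read length
            stagger = c <= read_length // 2
            for i in range(c):
                rows.append(
                    {
                        "transcript": gene,
                        "sample": sample,
                        "start": i if stagger else 0,
                        "end": (i if stagger else 0) + read_length,
                        "unique": True,
                        "complete": True,
                    }
                )
            if c and rng.random() < nonunique_fraction:
                rows.append(
                    {
                        "transcript": gene,
                        "sample": sample,
                        "start": 0,
                        "end": read_length,
                        "unique": False,
                        "complete": True,
                    }
                )
            if c and rng.random() < incomplete_fraction:
                rows.append(
                    {
                        "transcript": gene,
                        "sample": sample,
                        "start": 0,
                        "end": read_length,
                        "unique": True,
                        "complete": False,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["transcript", "sample", "start", "end", "unique", "complete"],
    )
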