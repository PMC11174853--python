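"""End-to-end orchestration: synthesis -> quantification -> count model ->
differential expression -> shift statistics -> coexpression -> enrichment,
plus the report computations (UP/DOWN ratios, cluster preservation, MAD
activity curves, chromosome distributions)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as coexpr
from . import count_model as cm
from . import diffexpr as de
from . import enrichment as enr
from . import quantify as qt
from . import shiftstats as ss
from .synthetic import SimulationConfig, SyntheticDataset, generate_dataset

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "report_updown_ratio",
    "report_cluster_preservation",
    "report_activity_curves",
    "mad",
]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    min_mean: int = 8
    min_bin_size: int = 30
    alpha: float = 0.05
    fc_floor: float = de.FC_FLOOR
    abundance_floor: float = de.ABUNDANCE_FLOOR
    n_permutations: int = ss.DEFAULT_N_PERMUTATIONS
    cluster_fold: float = 2.0
    min_set_size: int = ss.MIN_SET_SIZE
    run_shiftstats: bool = True
    run_coexpression: bool = True
    run_enrichment: bool = True
    coexpression_max_genes: int = 30

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self, seed=seed, simulation=replace(self.simulation, seed=seed)
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    normalized: qt.CountMatrix
    size_factors: pd.Series
    trend: cm.ThetaTrend
    estimates: pd.DataFrame
    de_table: pd.DataFrame
    report: dict
    shift_table: pd.DataFrame | None = None
    clusters: dict | None = None
    coexpression: dict | None = None
    enrichment_table: pd.DataFrame | None = None


def mad(values) -> float:
    """Median absolute deviation around the median."""
    x = np.asarray(values, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def report_updown_ratio(de_table: pd.DataFrame, timepoint: str) -> float:
    """count(UP) / count(DOWN) at one time point; inf when DOWN = 0 with
    UP > 0, NaN when both are zero."""
    sub = de_table[de_table["timepoint"] == timepoint]
    up = int((sub["status"] == "UP").sum())
    down = int((sub["status"] == "DOWN").sum())
    if down == 0:
        return float("inf") if up else float("nan")
    return up / down


def report_cluster_preservation(
    clusters_a: list[de.TimepointCluster],
    clusters_b: list[de.TimepointCluster],
) -> pd.DataFrame:
    """Per (timepoint, direction) preservation of A's clusters in B, plus the
    flow of non-preserved genes into the opposite-direction B cluster."""
    by_key_a: dict = {}
    for c in clusters_a:
        by_key_a.setdefault((c.timepoint, c.direction), set()).add(c.gene)
    by_key_b: dict = {}
    for c in clusters_b:
        by_key_b.setdefault((c.timepoint, c.direction), set()).add(c.gene)
    opposite = {
        "overexpressed": "underexpressed",
        "underexpressed": "overexpressed",
    }
    rows = []
    for (tp, direction), genes_a in sorted(by_key_a.items()):
        genes_b = by_key_b.get((tp, direction), set())
        lost = genes_a - genes_b
        flipped = {
            g
            for g in lost
            if any(
                g in by_key_b.get((tp2, opposite[direction]), set())
                for tp2 in {k[0] for k in by_key_b}
            )
        }
        rows.append(
            {
                "timepoint": tp,
                "direction": direction,
                "n_a": len(genes_a),
                "n_b": len(genes_b),
                "n_preserved": len(genes_a & genes_b),
                "preservation_rate": len(genes_a & genes_b) / len(genes_a),
                "n_flipped_direction": len(flipped),
            }
        )
    cols = [
        "timepoint", "direction", "n_a", "n_b", "n_preserved",
        "preservation_rate", "n_flipped_direction",
    ]
    return pd.DataFrame(rows, columns=cols)


def report_activity_curves(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per (line, timepoint) MAD of estimated mean counts (plot-ready)."""
    rows = []
    for (line, tp), grp in estimates.groupby(["line", "timepoint"], sort=False):
        rows.append(
            {"line": line, "timepoint": tp, "mad": mad(grp["mean"].to_numpy())}
        )
    return pd.DataFrame(rows, columns=["line", "timepoint", "mad"])


def _fit_trend(
    norm_counts: np.ndarray, config: PipelineConfig
) -> cm.ThetaTrend:
    """Dispersion trend from all (gene, line, timepoint) replicate cells."""
    cells = norm_counts.reshape(-1, norm_counts.shape[-1])
    cells = np.round(cells).astype(int)
    means = cells.mean(axis=1)
    bins = cm.pool_bins(
        means,
        list(cells),
        min_mean=config.min_mean,
        min_bin_size=config.min_bin_size,
    )
    return cm.fit_theta_trend(bins)


def _estimate_all(
    norm_counts: np.ndarray,
    genes,
    lines,
    timepoints,
    trend: cm.ThetaTrend,
    alpha: float,
) -> pd.DataFrame:
    n_g = norm_counts.shape[0]
    groups = [(line, tp) for line in lines for tp in timepoints]
    flat = norm_counts.reshape(n_g, len(groups), -1)
    table = cm.estimate_means_table(
        np.round(flat).astype(int),
        trend,
        alpha=alpha,
        genes=genes,
        samples=[f"{line}_{tp}" for line, tp in groups],
    )
    table["line"] = [groups[i % len(groups)][0] for i in range(len(table))]
    table["timepoint"] = [groups[i % len(groups)][1] for i in range(len(table))]
    return table


def _run_de(
    estimates: pd.DataFrame, trend: cm.ThetaTrend, config: PipelineConfig
) -> pd.DataFrame:
    lines = list(config.simulation.lines)
    wide_mean = estimates.pivot(index="gene", columns=["line", "timepoint"], values="mean")
    wide_ret = estimates.pivot(
        index="gene", columns=["line", "timepoint"], values="retained"
    )
    wide_exc = estimates.pivot(
        index="gene", columns=["line", "timepoint"], values="excluded"
    )
    rows = []
    for tp in config.simulation.timepoints:
        m_a = wide_mean[(lines[0], tp)]
        m_b = wide_mean[(lines[1], tp)]
        n_a = wide_ret[(lines[0], tp)]
        n_b = wide_ret[(lines[1], tp)]
        bad = wide_exc[(lines[0], tp)] | wide_exc[(lines[1], tp)]
        for gene in wide_mean.index:
            if bad[gene]:
                continue
            theta = trend.predict_theta((m_a[gene] + m_b[gene]) / 2.0)
            log2fc, p = de._wald_floored(
                m_a[gene],
                int(n_a[gene]),
                m_b[gene],
                int(n_b[gene]),
                theta,
                floor=config.abundance_floor,
            )
            rows.append(
                {
                    "gene": gene,
                    "timepoint": tp,
                    "mean_a": float(m_a[gene]),
                    "mean_b": float(m_b[gene]),
                    "log2fc": log2fc,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    return de.call_degs(
        table,
        abundance_floor=config.abundance_floor,
        fc_floor=config.fc_floor,
        alpha=config.alpha,
    )


def _expression_matrices(
    estimates: pd.DataFrame, config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """Per line, the (gene x timepoint) matrix of estimated means for genes
    expressed at >= the abundance floor in at least one sample."""
    wide = estimates.pivot(index="gene", columns=["line", "timepoint"], values="mean")
    expressed = (wide >= config.abundance_floor).any(axis=1)
    wide = wide[expressed]
    return {
        line: wide[line][list(config.simulation.timepoints)]
        for line in config.simulation.lines
    }


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute every enabled stage and assemble the summary report.

    When ``outdir`` is given, stage outputs are written as TSV/JSON under it
    together with a manifest; a stage failure still leaves the manifest of
    completed stages behind.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest = {"seed": config.seed, "stages_completed": completed}

    def _write_manifest():
        if out is not None:
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True)
            )

    try:
        result = _run_stages(config, out, completed)
    except Exception:
        _write_manifest()
        raise
    _write_manifest()
    return result


def _run_stages(config: PipelineConfig, out, completed) -> PipelineResult:
    sim = replace(config.simulation, seed=config.seed)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    report: dict = {"seed": config.seed}

    # --- synthesis ----------------------------------------------------------
    dataset = generate_dataset(sim)
    if out is not None:
        dataset.write_tsvs(out / "synthetic")
    completed.append("synthetic")

    # --- quantification / normalization ------------------------------------
    raw = qt.CountMatrix(
        values=dataset.count_table().astype(float),
        metadata=dataset.sample_metadata(),
    )
    normalized = qt.normalize_to_housekeeping(raw, dataset.housekeeping_gene_id)
    factors = qt.size_factors(normalized)
    report["size_factor_mean"] = float(factors.mean())
    report["size_factor_median"] = float(factors.median())
    completed.append("quantify")

    # --- count model --------------------------------------------------------
    n_g = len(dataset.genes)
    n_groups = len(sim.lines) * len(sim.timepoints)
    norm_counts = normalized.values.to_numpy().reshape(
        n_g, n_groups, sim.n_replicates
    )
    trend = _fit_trend(norm_counts, config)
    estimates = _estimate_all(
        norm_counts,
        dataset.genes,
        sim.lines,
        sim.timepoints,
        trend,
        config.alpha,
    )
    report["n_excluded_genes"] = int(estimates["excluded"].sum())
    report["n_outlier_trims"] = int(estimates["n_outliers"].sum())
    if out is not None:
        (out / "theta_trend.json").write_text(trend.to_json())
        estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
    completed.append("count_model")

    # --- differential expression -------------------------------------------
    de_table = _run_de(estimates, trend, config)
    timepoints = list(sim.timepoints)
    report["n_degs"] = int((de_table["status"] != "NONE").sum())
    report["degs_per_timepoint"] = {
        tp: int(
            ((de_table["timepoint"] == tp) & (de_table["status"] != "NONE")).sum()
        )
        for tp in timepoints
    }
    report["updown_ratio"] = {
        tp: report_updown_ratio(de_table, tp) for tp in timepoints
    }
    deg_genes = de_table.loc[de_table["status"] != "NONE", "gene"]
    chrom = pd.Series(dataset.chromosome)
    report["degs_per_chromosome"] = (
        chrom.loc[deg_genes.unique()].value_counts().sort_index().to_dict()
    )
    per_gene_tp = de_table[de_table["status"] != "NONE"].groupby("gene")[
        "timepoint"
    ].nunique()
    report["n_degs_all_timepoints"] = int((per_gene_tp == len(timepoints)).sum())
    if out is not None:
        de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    completed.append("diffexpr")

    expr = _expression_matrices(estimates, config)
    lines = list(sim.lines)

    # --- shift statistics ---------------------------------------------------
    shift_table = None
    clusters = None
    if config.run_shiftstats:
        rng_seed = seeds[0]
        rows = []
        log_expr = {line: ss.floor_log2(expr[line].to_numpy()) for line in lines}
        for i, tp in enumerate(timepoints):
            res = ss.permutation_test(
                log_expr[lines[0]][:, i],
                log_expr[lines[1]][:, i],
                sidedness="two",
                n_permutations=config.n_permutations,
                seed=rng_seed.spawn(1)[0],
                paired=True,
            )
            rows.append(
                {
                    "timepoint": tp,
                    "shift": res.shift,
                    "p_exact": res.p_exact,
                    "sidedness": res.sidedness,
                }
            )
        shift_table = pd.DataFrame(rows)
        report["transcriptome_shift"] = {
            r["timepoint"]: r["shift"] for r in rows
        }
        for line in lines:
            variances, _, _ = ss.diurnal_variance(expr[line].to_numpy())
            report[f"diurnal_variance_{line}"] = {
                tp: float(v) for tp, v in zip(timepoints, variances)
            }
        curves = report_activity_curves(
            estimates[~estimates["excluded"]]
        )
        report["activity_mad"] = {
            f"{r.line}_{r.timepoint}": r.mad for r in curves.itertuples()
        }

        # activity-change classification of DE events
        class_counts = {"enhancement": 0, "weakening": 0, "inversion": 0}
        deg_rows = de_table[de_table["status"] != "NONE"]
        for row in deg_rows.itertuples():
            if row.gene not in expr[lines[0]].index:
                continue
            cs_prof = ss.floor_log2(expr[lines[0]].loc[row.gene].to_numpy())
            ds_prof = ss.floor_log2(expr[lines[1]].loc[row.gene].to_numpy())
            kind = de.classify_activity_change(
                cs_prof, ds_prof, timepoints.index(row.timepoint)
            )
            class_counts[kind] += 1
        report["activity_change_counts"] = class_counts

        # time-point-associated clusters and their preservation
        clusters = {}
        ret_wide = estimates.pivot(
            index="gene", columns=["line", "timepoint"], values="retained"
        )
        for line in lines:
            entries: list[de.TimepointCluster] = []
            for gene in expr[line].index:
                entries.extend(
                    de.timepoint_association(
                        expr[line].loc[gene].to_numpy(),
                        ret_wide.loc[gene, line].to_numpy(),
                        trend,
                        gene=gene,
                        timepoints=timepoints,
                        fold=config.cluster_fold,
                        alpha=config.alpha,
                        floor=config.abundance_floor,
                    )
                )
            clusters[line] = entries
        preservation = report_cluster_preservation(
            clusters[lines[0]], clusters[lines[1]]
        )
        report["cluster_preservation"] = {
            f"{r.timepoint}_{r.direction}": r.preservation_rate
            for r in preservation.itertuples()
        }
        if out is not None:
            shift_table.to_csv(out / "shift_table.tsv", sep="\t", index=False)
            preservation.to_csv(
                out / "cluster_preservation.tsv", sep="\t", index=False
            )
        completed.append("shiftstats")

    # --- coexpression -------------------------------------------------------
    coexpression = None
    if config.run_coexpression:
        rng = np.random.default_rng(seeds[1])
        base = expr[lines[0]]
        spread = base.max(axis=1) / np.maximum(base.min(axis=1), 1.0)
        chosen = spread.sort_values(ascending=False).index[
            : config.coexpression_max_genes
        ]
        pair_r = {line: {} for line in lines}
        for line in lines:
            mat = np.maximum(expr[line].loc[chosen].to_numpy(), 1.0)
            for i in range(len(chosen)):
                for j in range(i + 1, len(chosen)):
                    res = coexpr.pair_correlation(
                        mat[i],
                        mat[j],
                        trend,
                        rng=rng,
                        gene_a=chosen[i],
                        gene_b=chosen[j],
                    )
                    pair_r[line][frozenset((chosen[i], chosen[j]))] = res.r
        cross_r = {}
        for gene in chosen:
            res = coexpr.pair_correlation(
                np.maximum(expr[lines[0]].loc[gene].to_numpy(), 1.0),
                np.maximum(expr[lines[1]].loc[gene].to_numpy(), 1.0),
                trend,
                rng=rng,
                gene_a=gene,
                gene_b=gene,
                basis="cross-line",
            )
            cross_r[gene] = res.r
        coexpressed_a = {
            pair for pair, r in pair_r[lines[0]].items() if coexpr.coexpression_call(r)
        }
        rate, preserved, coregulated = coexpr.preservation_and_coregulation(
            coexpressed_a, pair_r[lines[1]], cross_r
        )
        coexpression = {
            "pair_r": pair_r,
            "cross_line_r": cross_r,
            "coexpressed_a": coexpressed_a,
            "preserved": preserved,
            "coregulated": coregulated,
        }
        report["coexpression"] = {
            "n_pairs_tested": len(pair_r[lines[0]]),
            "n_coexpressed_a": len(coexpressed_a),
            "preservation_rate": rate,
            "n_coregulated": len(coregulated),
        }
        completed.append("coexpression")

    # --- enrichment ---------------------------------------------------------
    enrichment_table = None
    if config.run_enrichment:
        universe = set(expr[lines[0]].index)
        annotation_sets = []
        for term_class, mapping in [
            ("BP", dataset.bp_terms),
            ("pathway", dataset.pathway_terms),
        ]:
            by_term: dict = {}
            for g, terms in mapping.items():
                if g not in universe:
                    continue
                for t in terms:
                    by_term.setdefault(t, set()).add(g)
            for term, members in sorted(by_term.items()):
                annotation_sets.append(
                    enr.AnnotationSet(term, term_class, members, universe)
                )
        hit_sets = {}
        for tp in timepoints:
            for status in ("UP", "DOWN"):
                hits = set(
                    de_table.loc[
                        (de_table["timepoint"] == tp)
                        & (de_table["status"] == status),
                        "gene",
                    ]
                )
                if hits:
                    hit_sets[f"{tp}_{status}"] = hits
        enrichment_table = enr.enrich_all(
            hit_sets, annotation_sets, alpha=config.alpha
        )
        deg_set = set(deg_genes)
        paralogs = enr.paralog_enrichment(
            deg_set if deg_set else universe, dataset.paralog_cluster
        )
        report["paralogs_per_gene"] = paralogs.paralogs_per_gene
        report["paralogs_per_gene_adjusted"] = paralogs.paralogs_per_gene_adjusted
        report["n_enriched_terms"] = int(len(enrichment_table))
        if out is not None:
            enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        completed.append("enrichment")

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str)
        )
    return PipelineResult(
        config=config,
        dataset=dataset,
        normalized=normalized,
        size_factors=factors,
        trend=trend,
        estimates=estimates,
        de_table=de_table,
        report=report,
        shift_table=shift_table,
        clusters=clusters,
        coexpression=coexpression,
        enrichment_table=enrichment_table,
    )
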