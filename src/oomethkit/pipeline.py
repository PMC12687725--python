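"""End-to-end orchestration on synthetic scenarios, plus set statistics.

``run_pipeline`` executes the full analysis chain — simulation, window
counting, stable-gene normalization, spline-adjusted differential
expression with its shuffled-covariate control, allelic assignment, WGBS
QC/merging/clustering, lasso modelling, enrichment statistics and the
passive-dilution analytics — and writes a machine-readable report of
every recovery metric against the planted truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from oomethkit import allelic, cgi_model, core_io, cutrun_norm, diffexpr, methylome
from oomethkit import quantify, synthetic_data as synth

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((1e-5, "****"), (1e-3, "**"), (1e-2, "*"), (5e-2, "."))


def star_code(p: float) -> str:
    """Significance stars: **** p<=0.001%, ** p<=0.1%, * p<=1%, . p<=5%."""
    for thresh, code in STAR_THRESHOLDS:
        if p <= thresh:
            return code
    return ""


def fisher_overrep(
    members_in_cluster: int, members_total: int, cluster_size: int, universe: int
) -> tuple[float, float, str]:
    """Over/under-representation of a gene set in a cluster.

    Returns (obs/exp ratio, two-sided hypergeometric p, star code). The
    two-sided p sums the probabilities of all tables at most as likely as
    the observed one (the two-sided Fisher exact convention).
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    if members_in_cluster > min(members_total, cluster_size):
        raise ValueError("inconsistent counts")
    expected = members_total * cluster_size / universe
    ratio = members_in_cluster / expected if expected > 0 else np.inf
    rv = stats.hypergeom(universe, members_total, cluster_size)
    support = np.arange(max(0, members_total + cluster_size - universe),
                        min(members_total, cluster_size) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(members_in_cluster)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p = min(1.0, p)
    return ratio, p, star_code(p)


def jaccard_term_map(term_sets: dict[str, set]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-D MDS layout of gene-set similarity.

    Pairwise Jaccard distances (1 - |A&B|/|A|B|) between the named sets
    are embedded by classical MDS. Empty sets sit at distance 1 from
    everything (warned). Returns (coordinates, distance matrix).
    """
    names = list(term_sets)
    if len(names) < 2:
        raise ValueError("need >= 2 sets")
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = term_sets[names[i]], term_sets[names[j]]
            if not a or not b:
                logger.warning("jaccard_term_map: empty set among %s/%s",
                               names[i], names[j])
                d = 1.0
            else:
                union = len(a | b)
                d = 1.0 - len(a & b) / union
            dist[i, j] = dist[j, i] = d
    coords, _ = methylome.classical_mds(dist, 2)
    cdf = pd.DataFrame(coords, index=names, columns=["mds1", "mds2"])
    ddf = pd.DataFrame(dist, index=names, columns=names)
    return cdf, ddf


# ---------------------------------------------------------------------------
# scenario configuration


@dataclass
class PipelineConfig:
    """Default synthetic scenario; every stage draws from ``seed``."""

    scenario: str = "default"
    seed: int = 0
    out_dir: str = "oomethkit_out"
    n_genes: int = 60
    n_cgis: int = 80
    n_tiles: int = 10
    n_rna_replicates: int = 6
    rna_depth: float = 1e6
    cutrun_depth: float = 5e5
    cutrun_background: float = 0.2
    wgbs_coverage: float = 30.0
    n_cpg_per_region: int = 8
    genotypes: tuple[str, ...] = ("ctrl", "aKO_bKO")
    k_cgi_clusters: int = 3
    strict: bool = False

    def subseed(self, tag: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, tag])


def _seed_int(cfg: PipelineConfig, tag: int) -> int:
    return int(cfg.subseed(tag).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the default scenario end to end; returns the report dict.

    Writes ``report.json``, the DE table, cluster assignments, lasso
    summary and QC report under ``config.out_dir``. With
    ``config.strict``, raises ``RuntimeError`` if any recovery property
    fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"scenario": config.scenario, "seed": config.seed}

    ann = synth.simulate_annotation(
        n_genes=config.n_genes, n_cgis=config.n_cgis, n_tiles=config.n_tiles,
        seed=_seed_int(config, 1),
    )
    params = synth.EffectParams()
    truth_seed = _seed_int(config, 2)
    truths = {
        g: synth.simulate_truth(ann, g, params, seed=truth_seed)
        for g in config.genotypes
    }
    ctrl, mut = config.genotypes[0], config.genotypes[1]

    # --- CUT&RUN normalization recovery under depth distortion -------------
    region_windows = [
        core_io.GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), id=rid)
        for rid, r in truths[ctrl].regions.iterrows()
    ]
    depths = {ctrl: config.cutrun_depth, mut: 3 * config.cutrun_depth}
    tables = []
    for i, g in enumerate((ctrl, mut)):
        spec = synth.LibrarySpec(
            genotype=g, depth=depths[g],
            background_rate=config.cutrun_background,
            seed=_seed_int(config, 10 + i),
        )
        tables.append(
            synth.simulate_cutrun_counts(truths[g], region_windows, "h3k36me2", spec)
        )
    cutrun = synth.combine_libraries(tables)
    stable_ids = [
        f"gb_{gid}" for gid, row in truths[ctrl].gene_expr.iterrows()
        if not row["derepressed"]
    ]
    normalized, factors = cutrun_norm.normalize_libraries(cutrun, stable_ids)
    stable_means = normalized.loc[stable_ids].mean(axis=0)
    norm_dev = float(stable_means.max() / stable_means.min() - 1.0)
    report["normalization"] = {
        "factors": factors.to_dict(),
        "stable_mean_max_rel_dev": norm_dev,
    }

    # --- differential expression with diameter spline ----------------------
    rng = np.random.default_rng(_seed_int(config, 20))
    rna_tables = []
    for g in (ctrl, mut):
        for r in range(config.n_rna_replicates):
            spec = synth.LibrarySpec(
                genotype=g, depth=config.rna_depth,
                diameter=float(rng.uniform(58, 78)), replicate=r + 1,
                seed=_seed_int(config, 30) + 131 * r + (0 if g == ctrl else 17),
            )
            gene_windows = [gg for gg in ann.genes if gg.chrom == "chr1"]
            rna_tables.append(
                synth.simulate_counts(truths[g], gene_windows, "rnaseq", spec)
            )
    rna = synth.combine_libraries(rna_tables)
    model = diffexpr.DifferentialExpressionModel(rna, preset="go_diameter")
    real, shuffled, overfit = model.fit_shuffled(
        mut, ctrl, "diameter", seed=_seed_int(config, 21)
    )
    real.to_tsv(out / "de_table.tsv")
    derepressed = truths[mut].gene_expr.query("derepressed").index
    tested = real.table.index.intersection(derepressed)
    med_lfc = float(real.table.loc[tested, "log2fc"].median()) if len(tested) else np.nan
    report["diffexpr"] = {
        "n_up": real.n_up, "n_down": real.n_down,
        "n_up_shuffled": shuffled.n_up, "n_down_shuffled": shuffled.n_down,
        "overfit_flag": bool(overfit),
        "median_log2fc_derepressed": med_lfc,
        "expected_log2fc_derepressed": float(
            np.log2(synth.GENOTYPE_EFFECTS[mut][2])
        ),
    }

    # --- allelic assignment -------------------------------------------------
    reads = synth.simulate_hybrid_reads(
        20_000, (0.45, 0.45), ("poisson", 2.0), error_rate=0.0,
        seed=_seed_int(config, 40),
        feature_ids=[g.id for g in ann.genes[:10]],
    )
    labels = allelic.assign_reads(reads)
    informative = reads.reads["true_origin"] != "none"
    acc = float(
        (labels[informative] == reads.reads.loc[informative, "true_origin"]).mean()
    )
    report["allelic"] = {"assignment_accuracy": acc}

    # --- WGBS QC, merging, clustering --------------------------------------
    wgbs_libs, genos = [], []
    for i, g in enumerate((ctrl, ctrl, mut, mut)):
        spec = synth.LibrarySpec(
            genotype=g, depth=2e7, coverage=config.wgbs_coverage,
            conversion_failure=0.005, replicate=i + 1,
            seed=_seed_int(config, 50) + i,
        )
        wgbs_libs.append(
            synth.simulate_wgbs(truths[g], spec, config.n_cpg_per_region, 2_000)
        )
        genos.append(g)
    # one library with failed conversion, one undersized
    bad_conv = synth.LibrarySpec(genotype=ctrl, depth=2e7, conversion_failure=0.08,
                                 coverage=config.wgbs_coverage, replicate=9,
                                 seed=_seed_int(config, 51))
    bad_size = synth.LibrarySpec(genotype=ctrl, depth=5e6, conversion_failure=0.005,
                                 coverage=config.wgbs_coverage, replicate=10,
                                 seed=_seed_int(config, 52))
    wgbs_libs += [
        synth.simulate_wgbs(truths[ctrl], bad_conv, config.n_cpg_per_region, 2_000),
        synth.simulate_wgbs(truths[ctrl], bad_size, config.n_cpg_per_region, 2_000),
    ]
    genos += [ctrl, ctrl]
    qc = methylome.qc_libraries(wgbs_libs, genotypes=genos,
                                seed=_seed_int(config, 53))
    qc.to_csv(out / "wgbs_qc.tsv", sep="\t")
    passing = [lib for lib, ok in zip(wgbs_libs, qc["pass"]) if ok]
    pass_genos = [g for g, ok in zip(genos, qc["pass"]) if ok]
    merged = {
        g: methylome.merge_genotype(
            [lib for lib, gg in zip(passing, pass_genos) if gg == g], name=g
        )
        for g in (ctrl, mut)
    }
    cgi_windows = core_io.make_windows(ann, "cgi_center", width=533)
    levels = pd.DataFrame({
        g: methylome.methylation_levels(merged[g], cgi_windows) for g in (ctrl, mut)
    })
    global_meth = {
        g: float(100.0 * m.calls.query("context == 'CpG'")["methylated"].sum()
                 / m.calls.query("context == 'CpG'")["total"].sum())
        for g, m in merged.items()
    }
    report["wgbs"] = {
        "qc_pass": qc["pass"].to_dict(),
        "global_mcpg_pct": global_meth,
    }
    clusters = methylome.cluster_cgi_methylomes(
        levels, k=config.k_cgi_clusters, seed=_seed_int(config, 54)
    )
    clusters.to_csv(out / "cgi_clusters.tsv", sep="\t")
    truth_labels = truths[ctrl].regions.loc[clusters.index, "meth_class"]
    ari = float(adjusted_rand_score(truth_labels, clusters))
    report["cgi_clusters"] = {"k": config.k_cgi_clusters, "ari_vs_planted": ari}

    # --- lasso models -------------------------------------------------------
    cgis = truths[ctrl].regions.query("kind == 'cgi'").index
    feats = pd.DataFrame({
        "h3k4me3": truths[ctrl].regions.loc[cgis, "h3k4me3"],
        "h3k36me3": truths[ctrl].regions.loc[cgis, "h3k36me3"],
        "h3k36me2": truths[ctrl].regions.loc[cgis, "h3k36me2"],
        "h2ak119u1": truths[ctrl].regions.loc[cgis, "h2ak119u1"],
        "h3k27me3": truths[ctrl].regions.loc[cgis, "h3k27me3"],
    })
    y = 100.0 * truths[ctrl].regions.loc[cgis, "meth_frac"]  # mCpG/CpG %
    basal = cgi_model.CGILassoModel.from_dataframe(
        feats, y, response_name="ctrl CGI methylation (%)"
    ).fit(seed=_seed_int(config, 60))
    y_mut = truths[mut].regions.loc[cgis, "h3k36me2"]
    y_wt = truths[ctrl].regions.loc[cgis, "h3k36me2"]
    diff_feats = feats.drop(columns=["h3k36me2"])
    diff = cgi_model.CGILassoModel.from_dataframe(
        diff_feats, y_mut, y_wt=y_wt, response_name="differential H3K36me2"
    ).fit(seed=_seed_int(config, 61))
    (out / "lasso_summary.txt").write_text(
        basal.summary() + "\n\n" + diff.summary() + "\n"
    )
    diff_top = diff.nonzero(exclude=("wt_level",))
    report["lasso"] = {
        "basal_r2": basal.r_squared,
        "basal_coef": basal.coef.to_dict(),
        "differential_r2": diff.r_squared,
        "differential_top": diff_top.to_dict(),
    }

    # --- enrichment of upregulated genes in methylation-gain clusters ------
    gain = (levels[mut] - levels[ctrl]).reindex(clusters.index)
    gain_cluster = int(gain.groupby(clusters).mean().idxmax())
    cluster_cgis = clusters.index[clusters == gain_cluster]
    cgi_to_gene = {
        f"cgi_prom_{g.id}": g.id for g in ann.genes
        if f"cgi_prom_{g.id}" in set(clusters.index)
    }
    cluster_genes = {cgi_to_gene[c] for c in cluster_cgis if c in cgi_to_gene}
    universe_genes = set(cgi_to_gene.values())
    up = set(real.de_genes("up")) & universe_genes
    ratio, p, code = fisher_overrep(
        len(up & cluster_genes), len(up), len(cluster_genes), len(universe_genes)
    )
    report["enrichment"] = {
        "up_in_gain_cluster_obs_exp": ratio, "p": p, "stars": code,
    }

    # --- passive dilution ---------------------------------------------------
    m_pre, fold_pre = methylome.passive_dilution(
        methylome.DilutionModel(0.8, 2, 0.0, post_replication=False)
    )
    m_post, fold_post = methylome.passive_dilution(
        methylome.DilutionModel(0.8, 2, 0.0, post_replication=True)
    )
    report["passive_dilution"] = {
        "fold_pre_replication": fold_pre, "fold_post_replication": fold_post,
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    if config.strict:
        _strict_checks(report)
    return report


def _strict_checks(report: dict) -> None:
    problems = []
    if report["normalization"]["stable_mean_max_rel_dev"] > 0.02:
        problems.append("stable-window means not equalized within 2%")
    if report["allelic"]["assignment_accuracy"] < 1.0:
        problems.append("allelic assignment not perfect at error rate 0")
    if report["cgi_clusters"]["ari_vs_planted"] < 0.9:
        problems.append("CGI clustering missed planted classes")
    if abs(report["passive_dilution"]["fold_pre_replication"] - 4.0) > 1e-9:
        problems.append("passive-dilution analytics wrong")
    if problems:
        raise RuntimeError("strict checks failed: " + "; ".join(problems))
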