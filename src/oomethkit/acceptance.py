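"""End-to-end recovery checks against planted ground truth.

Each function here rebuilds a synthetic scenario from scratch, runs the
corresponding analysis stage, and measures how well it recovers what was
planted. They back both the reproducibility script
(``scripts/acceptance.py``) and the acceptance test suite, so the numbers
reported and the properties tested are computed by exactly one code path.

All randomness derives from a single master seed via
:func:`numpy.random.SeedSequence` spawning, so the whole battery is
reproducible from one integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from oomethkit import allelic, cgi_model, cutrun_norm, methylome
from oomethkit import synthetic_data as synth
from oomethkit.core_io import GenomicInterval
from oomethkit.diffexpr import DifferentialExpressionModel
from oomethkit.methylome import DilutionModel, passive_dilution


def _sub(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# passive dilution (analytic)


def check_passive_dilution() -> dict:
    """Fold reduction from oocyte to four-cell with no maintenance.

    Two cleavage divisions separate the oocyte from a four-cell embryo;
    a cell captured after its next S phase has seen one more replication,
    giving the 4- to 8-fold window for purely passive loss.
    """
    _, fold_pre = passive_dilution(DilutionModel(0.8, 2, 0.0, post_replication=False))
    _, fold_post = passive_dilution(DilutionModel(0.8, 2, 0.0, post_replication=True))
    return {"fold_pre_replication": fold_pre, "fold_post_replication": fold_post}


# ---------------------------------------------------------------------------
# stable-gene normalization recovery


def check_normalization(seed: int, n_bins: int = 2_000) -> dict:
    """Depth/background distortion recovery on intergenic tile bins.

    Two libraries of the same mark differ 3x in depth and 2x in uniform
    background. Stable windows are gene bodies with zero planted
    H3K36me2 gain; tile bins carry planted mutant-over-control gains.
    Reports the relative spread of stable-window means after
    normalization and the relative error of the median recovered log2
    ratio at differential bins after the 15th-centile min-shift.
    """
    s = _sub(seed, 2)
    ann = synth.simulate_annotation(n_genes=60, n_cgis=20, n_tiles=n_bins // 20,
                                    seed=s)
    genome = sum(ann.chrom_sizes.values())
    params = synth.EffectParams()
    tc = synth.simulate_truth(ann, "ctrl", params, seed=s)
    tm = synth.simulate_truth(ann, "aKO_bKO", params, seed=s)
    gain = tm.regions["h3k36me2"] - tc.regions["h3k36me2"]
    gb = tc.regions.query("kind == 'genebody'").index
    stable_ids = [i for i in gb if gain[i] == 0]
    bins = tc.regions.query("kind == 'tile_bin'").index
    windows = [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), id=rid)
        for rid, r in tc.regions.loc[list(stable_ids) + list(bins)].iterrows()
    ]
    lib_c = synth.LibrarySpec(genotype="ctrl", depth=2e6, background_rate=0.1,
                              seed=_sub(seed, 21))
    lib_m = synth.LibrarySpec(genotype="aKO_bKO", depth=6e6, background_rate=0.2,
                              seed=_sub(seed, 22))
    t_c = synth.simulate_cutrun_counts(tc, windows, "h3k36me2", lib_c, genome)
    t_m = synth.simulate_cutrun_counts(tm, windows, "h3k36me2", lib_m, genome)
    comb = synth.combine_libraries([t_c, t_m])
    norm, factors = cutrun_norm.normalize_libraries(comb, stable_ids)
    sm = norm.loc[stable_ids].mean(axis=0)
    stable_dev = float(sm.max() / sm.min() - 1.0)
    sh_c = cutrun_norm.min_shift(norm.loc[bins].iloc[:, 0].to_numpy())
    sh_m = cutrun_norm.min_shift(norm.loc[bins].iloc[:, 1].to_numpy())
    planted = np.log2(
        tm.regions.loc[bins, "h3k36me2"] / tc.regions.loc[bins, "h3k36me2"]
    )
    sel = (
        (np.isfinite(planted) & (gain[bins] > 0)).to_numpy()
        & (sh_c > 20) & (sh_m > 20)
    )
    measured = np.median(np.log2(sh_m[sel] / sh_c[sel]))
    target = np.median(planted.to_numpy()[sel])
    return {
        "n_bins": int(len(bins)),
        "stable_mean_max_rel_dev": stable_dev,
        "planted_median_log2_ratio": float(target),
        "measured_median_log2_ratio": float(measured),
        "logratio_rel_err": float(abs(measured - target) / abs(target)),
    }


# ---------------------------------------------------------------------------
# differential expression calibration


def check_de_null(seed: int, n_genes: int = 2_000) -> dict:
    """Type-I error of the NB GLM LRT on a null 12-sample cohort."""
    genos = ["ctrl"] * 6 + ["mut"] * 6
    tab = synth.simulate_expression_matrix(genos, n_genes=n_genes, dispersion=0.1,
                                           seed=_sub(seed, 3))
    res = DifferentialExpressionModel(tab).fit("mut", "ctrl")
    p = res.table["pvalue"].dropna()
    return {"n_genes": int(len(p)), "type1_error": float((p < 0.05).mean())}


def check_de_planted(seed: int, n_genes: int = 2_000, n_de: int = 50) -> dict:
    """Recovery of a planted 4-fold (log2FC = 2) expression change."""
    genos = ["ctrl"] * 6 + ["mut"] * 6
    tab = synth.simulate_expression_matrix(
        genos, n_genes=n_genes, n_de=n_de, log2fc=2.0, dispersion=0.1,
        seed=_sub(seed, 4),
    )
    res = DifferentialExpressionModel(tab).fit("mut", "ctrl")
    de = tab.extras["is_de"].reindex(res.table.index).fillna(False)
    return {
        "n_planted": int(de.sum()),
        "median_log2fc": float(res.table.loc[de, "log2fc"].median()),
    }


def check_de_confounding(seed: int, n_genes: int = 2_000) -> dict:
    """Spline adjustment vs no adjustment under covariate confounding.

    Pseudotime-like covariate overlaps genotype; 30% of genes respond to
    it. Reports raw false-positive counts (no genotype effect planted)
    with and without the natural-spline term, and the shuffled-covariate
    control call counts.
    """
    genos = ["ctrl"] * 6 + ["mut"] * 6
    rng = np.random.default_rng(_sub(seed, 5))
    cov = np.concatenate([rng.uniform(0, 0.6, 6), rng.uniform(0.4, 1.0, 6)])
    tab = synth.simulate_expression_matrix(
        genos, n_genes=n_genes, covariate=cov, covariate_frac=0.3,
        covariate_strength=1.5, dispersion=0.1, seed=_sub(seed, 51),
    )
    spline = DifferentialExpressionModel(tab, preset="go_diameter")
    plain = DifferentialExpressionModel(tab, preset="fgo")
    fp_spline = int((spline.fit("mut", "ctrl").table["pvalue"] < 0.05).sum())
    fp_plain = int((plain.fit("mut", "ctrl").table["pvalue"] < 0.05).sum())

    # shuffled-covariate overfitting control on a balanced design: the
    # covariate affects genes but is independent of genotype, so the
    # spline has real variation to absorb and permuting it must not
    # manufacture DE calls (in the confounded design above, permuting the
    # covariate by construction floods the genotype term instead)
    cov_bal = rng.permutation(np.linspace(0, 1, len(genos)))
    tab_bal = synth.simulate_expression_matrix(
        genos, n_genes=n_genes, covariate=cov_bal, covariate_frac=0.3,
        covariate_strength=1.5, dispersion=0.1, seed=_sub(seed, 53),
    )
    bal = DifferentialExpressionModel(tab_bal, preset="go_diameter")
    real, shuffled, overfit = bal.fit_shuffled("mut", "ctrl", "diameter",
                                               seed=_sub(seed, 52))
    return {
        "n_genes": n_genes,
        "fp_spline": fp_spline,
        "fp_no_spline": fp_plain,
        "fp_reduction_fold": float(fp_plain / max(fp_spline, 1)),
        "de_calls_real": len(real.de_genes()),
        "de_calls_shuffled": len(shuffled.de_genes()),
        "overfit_flag": bool(overfit),
    }


# ---------------------------------------------------------------------------
# lasso recovery


def _lasso_scenario(seed: int, planted_r2: float):
    ann = synth.simulate_annotation(n_genes=120, n_cgis=400, n_tiles=5,
                                    seed=_sub(seed, 6))
    params = synth.EffectParams(noise_sd=0.0)
    truth = synth.simulate_truth(ann, "ctrl", params, seed=_sub(seed, 6))
    reg = truth.regions[(truth.regions["kind"] == "cgi") & ~truth.regions["clamped"]]
    lin = 100.0 * reg["meth_frac"].to_numpy()  # respond on the % scale
    noise_sd = np.sqrt(lin.var() * (1 - planted_r2) / planted_r2)
    rng = np.random.default_rng(_sub(seed, 61))
    y = pd.Series(lin + rng.normal(0, noise_sd, len(lin)), index=reg.index)
    feats = reg[["h3k36me2", "h3k36me3", "h3k4me3", "h2ak119u1", "h3k27me3"]]
    return feats, y


def check_lasso_recovery(seed: int) -> dict:
    """Planted-coefficient recovery of the CGI methylation lasso.

    At planted R^2 = 0.8 the fit must recover that R^2 and the signs of
    all three planted effects (+H3K36me2, +H3K36me3, -H3K4me3); at
    planted R^2 = 0.34 (the differential-signal regime) the two largest
    effects must keep their signs. Also verifies the 1-SE rule inequality
    on the CV curve and the KKT conditions of the selected solution.
    """
    out: dict = {}
    for target, label in ((0.8, "high"), (0.34, "low")):
        feats, y = _lasso_scenario(seed, target)
        fit = cgi_model.CGILassoModel.from_dataframe(feats, y).fit(
            seed=_sub(seed, 62)
        )
        signs_ok = (
            fit.coef["h3k36me2"] > 0 and fit.coef["h3k36me3"] > 0
            and fit.coef["h3k4me3"] < 0
        )
        top2_ok = fit.coef["h3k36me2"] > 0 and fit.coef["h3k36me3"] > 0
        i_min = int(np.argmin(fit.cv_mean))
        i_sel = list(fit.lambdas).index(fit.lambda_1se)
        one_se_ok = (
            fit.cv_mean[i_sel] <= fit.cv_mean[i_min] + fit.cv_se[i_min]
            and fit.lambda_1se >= fit.lambda_min
        )
        x = cgi_model.standardize(feats).x.to_numpy()
        kkt = cgi_model.kkt_violation(
            x, y.to_numpy(),
            float(fit.intercept), fit.coef.to_numpy(), fit.lambda_1se,
        )
        out[f"r2_{label}"] = float(fit.r_squared)
        out[f"planted_r2_{label}"] = target
        out[f"all_signs_ok_{label}"] = bool(signs_ok)
        out[f"top2_signs_ok_{label}"] = bool(top2_ok)
        out[f"one_se_rule_ok_{label}"] = bool(one_se_ok)
        out[f"kkt_violation_{label}"] = float(kkt)
        out[f"n_cgis_{label}"] = int(len(y))
    return out


def check_differential_lasso(seed: int) -> dict:
    """Sign recovery of the wild-type-as-predictor differential design."""
    s = _sub(seed, 7)
    ann = synth.simulate_annotation(n_genes=120, n_cgis=400, n_tiles=5, seed=s)
    params = synth.EffectParams(noise_sd=0.0)
    ctrl = synth.simulate_truth(ann, "ctrl", params, seed=s)
    mut = synth.simulate_truth(ann, "aKO_bKO", params, seed=s)
    cgis = ctrl.regions.query("kind == 'cgi'").index
    feats = ctrl.regions.loc[cgis, ["h3k4me3", "h3k36me3", "h2ak119u1", "h3k27me3"]]
    y_wt = ctrl.regions.loc[cgis, "h3k36me2"]
    y_mut = mut.regions.loc[cgis, "h3k36me2"]
    ft = cgi_model.standardize(feats)
    f1 = cgi_model.differential_lasso(y_mut, ft, y_wt, seed=_sub(seed, 71))
    f2 = cgi_model.differential_lasso(y_mut, ft, y_wt, seed=_sub(seed, 71),
                                      mode="residualize")
    nz = f1.nonzero(exclude=("wt_level",))
    top1 = set(nz.index[:3])
    top2 = set(f2.nonzero().index[:3])
    return {
        "n_cgis": int(len(cgis)),
        "h2ak119u1_coef": float(nz.get("h2ak119u1", 0.0)),
        "h3k4me3_coef": float(nz.get("h3k4me3", 0.0)),
        "mode_top3_overlap": int(len(top1 & top2)),
    }


# ---------------------------------------------------------------------------
# allelic assignment


def check_allelic(seed: int, n_reads: int = 20_000) -> dict:
    """Assignment accuracy, swap symmetry and methylation recovery."""
    reads = synth.simulate_hybrid_reads(
        n_reads, (0.45, 0.45), ("poisson", 2.0), error_rate=0.0,
        seed=_sub(seed, 8),
    )
    labels = allelic.assign_reads(reads)
    informative = reads.reads["true_origin"] != "none"
    accuracy = float(
        (labels[informative] == reads.reads.loc[informative, "true_origin"]).mean()
    )
    swapped = allelic.ReadMismatchTable(
        reads.reads.rename(columns={
            "mismatches_maternal": "mismatches_paternal",
            "mismatches_paternal": "mismatches_maternal",
        })
    )
    swap_map = {"maternal": "paternal", "paternal": "maternal",
                "undefined": "undefined"}
    swap_exact = bool(
        (allelic.assign_reads(swapped) == labels.map(swap_map)).all()
    )

    # allelic methylation: 90%/10% planted, ~200 informative calls/allele
    region = GenomicInterval("chr1", 0, 10_000, id="r")
    rng = np.random.default_rng(_sub(seed, 81))
    rows = []
    for hap, frac in (("maternal", 0.9), ("paternal", 0.1)):
        meth = rng.binomial(1, frac, size=200)
        for i, m in enumerate(meth):
            rows.append(("chr1", i, "CpG", int(m), 1, hap))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "context", "methylated",
                                        "total", "haplotype"])
    am = allelic.allelic_methylation(calls, [region])
    return {
        "n_reads": n_reads,
        "assignment_accuracy": accuracy,
        "swap_symmetry_exact": swap_exact,
        "maternal_meth_err_points": float(abs(am.loc["r", "maternal"] - 90.0)),
        "paternal_meth_err_points": float(abs(am.loc["r", "paternal"] - 10.0)),
    }


# ---------------------------------------------------------------------------
# WGBS QC


def check_wgbs_qc(seed: int) -> dict:
    """Conversion/size thresholds, planted MDS outlier, merge identity."""
    s = _sub(seed, 9)
    ann = synth.simulate_annotation(n_genes=40, n_cgis=60, n_tiles=6, seed=s)
    params = synth.EffectParams()
    truth = synth.simulate_truth(ann, "ctrl", params, seed=s)
    good = [
        synth.simulate_wgbs(
            truth,
            synth.LibrarySpec(depth=2e7, coverage=15, conversion_failure=0.005,
                              seed=_sub(seed, 90 + i)),
            4, 1_500,
        )
        for i in range(3)
    ]
    for i, lib in enumerate(good):
        lib.name = f"good{i}"
    badconv = synth.simulate_wgbs(
        truth, synth.LibrarySpec(depth=2e7, coverage=15, conversion_failure=0.08,
                                 seed=_sub(seed, 95)), 4, 1_500)
    badconv.name = "badconv"
    okconv = synth.simulate_wgbs(
        truth, synth.LibrarySpec(depth=2e7, coverage=15, conversion_failure=0.03,
                                 seed=_sub(seed, 96)), 4, 1_500)
    okconv.name = "okconv"
    small = synth.simulate_wgbs(
        truth, synth.LibrarySpec(depth=5e6, coverage=15, conversion_failure=0.005,
                                 seed=_sub(seed, 97)), 4, 1_500)
    small.name = "small"
    flat = synth.EffectParams(beta0=0.8, beta_k36me2=0, beta_k36me3=0,
                              beta_k4me3=0, noise_sd=0)
    odd_truth = synth.simulate_truth(ann, "ctrl", flat, seed=s)
    outlier = synth.simulate_wgbs(
        odd_truth, synth.LibrarySpec(depth=2e7, coverage=15,
                                     conversion_failure=0.005,
                                     seed=_sub(seed, 98)), 4, 1_500)
    outlier.name = "outlier"
    libs = good + [badconv, okconv, small, outlier]
    report = methylome.qc_libraries(
        libs, genotypes=["ctrl"] * len(libs), seed=_sub(seed, 99)
    )
    expected = {"good0": True, "good1": True, "good2": True, "badconv": False,
                "okconv": True, "small": False, "outlier": False}
    correct = np.mean([report.loc[k, "pass"] == v for k, v in expected.items()])
    merged = methylome.merge_genotype(good)
    pooled = merged.calls.query("context == 'CpG'")
    lhs = pooled["methylated"].sum() / pooled["total"].sum()
    rhs = (
        sum(l.calls.query("context == 'CpG'")["methylated"].sum() for l in good)
        / sum(l.calls.query("context == 'CpG'")["total"].sum() for l in good)
    )
    return {
        "n_libraries": len(libs),
        "qc_decisions_correct_frac": float(correct),
        "outlier_flagged": bool(not report.loc["outlier", "pass"]),
        "merge_weighted_mean_abs_diff": float(abs(lhs - rhs)),
    }


# ---------------------------------------------------------------------------
# clustering


def check_clustering(seed: int) -> dict:
    """ARI on well-separated planted classes (k = 3 CGI methylomes, k = 8
    gene chromatin profiles) plus seed determinism."""
    rng = np.random.default_rng(_sub(seed, 10))
    # k=3: CGI methylation levels across two conditions
    levels, truth3 = [], []
    for i, (m_ctrl, m_mut) in enumerate(((0, 50), (60, 62), (3, 3))):
        n = 60
        levels.append(np.clip(
            np.column_stack([rng.normal(m_ctrl, 2.0, n), rng.normal(m_mut, 2.0, n)]),
            0, 100))
        truth3 += [i] * n
    df3 = pd.DataFrame(np.vstack(levels), columns=["ctrl", "mut"])
    lab3 = methylome.cluster_cgi_methylomes(df3, k=3, seed=_sub(seed, 101))
    ari3 = float(adjusted_rand_score(truth3, lab3))
    # k=8: standardized 40-column chromatin feature profiles per gene
    centers = rng.normal(0, 1, size=(8, 40)) * 12.0
    rows, truth8 = [], []
    for i in range(8):
        n = 30
        rows.append(centers[i] + rng.normal(0, 1, size=(n, 40)))
        truth8 += [i] * n
    x8 = np.vstack(rows)
    x8 = (x8 - x8.mean(0)) / x8.std(0)
    from oomethkit.quantify import kmeans_cluster

    lab8a, _ = kmeans_cluster(x8, 8, n_starts=100, seed=_sub(seed, 102))
    lab8b, _ = kmeans_cluster(x8, 8, n_starts=100, seed=_sub(seed, 102))
    ari8 = float(adjusted_rand_score(truth8, lab8a))
    return {
        "n_cgis_k3": len(truth3),
        "n_genes_k8": len(truth8),
        "ari_k3": ari3,
        "ari_k8": ari8,
        "deterministic": bool((lab8a == lab8b).all()),
    }


# ---------------------------------------------------------------------------
# global methylation recovery


def check_global_methylation(seed: int) -> dict:
    """Pooled mCpG/CpG recovery of flat planted methylomes.

    Control and double-mutant global levels are planted as simulation
    parameters (35.8% and 58.8%) and re-estimated from simulated calls.
    """
    s = _sub(seed, 11)
    ann = synth.simulate_annotation(n_genes=40, n_cgis=60, n_tiles=6, seed=s)
    out = {}
    for label, level, tag in (("ctrl", 0.358, 111), ("double_mutant", 0.588, 112)):
        params = synth.EffectParams(beta0=level, beta_k36me2=0, beta_k36me3=0,
                                    beta_k4me3=0, noise_sd=0)
        truth = synth.simulate_truth(ann, "ctrl", params, seed=s)
        calls = synth.simulate_wgbs(
            truth,
            synth.LibrarySpec(coverage=30, conversion_failure=0.0,
                              seed=_sub(seed, tag)),
            10, 10,
        )
        cpg = calls.calls.query("context == 'CpG'")
        out[f"global_mcpg_{label}_pct"] = float(
            100.0 * cpg["methylated"].sum() / cpg["total"].sum()
        )
        out["n_cpg_calls"] = int(cpg["total"].sum())
    return out
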