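"""Negative-binomial differential expression with spline covariates.

The model is the one used for single-oocyte and single-embryo RNA-seq:
per-gene negative-binomial GLMs with a log link and log-library-size
offset, a design of genotype indicators (optionally genotype:sex
interactions) plus a natural cubic spline basis in a continuous nuisance
covariate — oocyte diameter for growing oocytes, transcriptional
pseudotime for two-cell embryos — likelihood-ratio tests of the genotype
terms, and Benjamini-Hochberg correction. A shuffled-covariate rerun
controls for spline overfitting.

Exposed statsmodels-style: build a :class:`DifferentialExpressionModel`
from a count table, call :meth:`~DifferentialExpressionModel.fit` to get a
:class:`DEResults` with per-gene estimates and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from oomethkit.quantify import CountTable, cpm

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

#: default DE call thresholds: |log2FC| > 1 and adjusted p < 0.05
DE_LFC_THRESH = 1.0
DE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# building blocks


def filter_expressed(
    table: CountTable, min_cpm: float = 1.0, min_samples: int = 3
) -> CountTable:
    """Keep genes with CPM >= min_cpm in >= min_samples libraries."""
    keep = (cpm(table) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        logger.warning("filter_expressed: no genes pass the expression filter")
    return table.subset_regions(table.region_ids[keep])


def spline_basis(
    x: np.ndarray, df: int = 3, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Boundary knots sit at min/max of ``x`` and the ``df - 1`` interior
    knots at equally spaced quantiles, unless explicit ``knots`` (interior
    + boundary, sorted) are given. The basis spans linear functions of
    ``x`` and has zero second derivative at and beyond the boundary knots
    (the usual truncated-power construction of natural splines).
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; spline basis undefined")
    if knots is None:
        qs = np.linspace(0, 1, df + 1)
        knots = np.quantile(x, qs)
    knots = np.unique(np.asarray(knots, dtype=float))
    if len(knots) < 2:
        raise ValueError("need at least 2 distinct knots")
    if len(knots) != df + 1:
        raise ValueError(f"df={df} requires {df + 1} distinct knots, got {len(knots)}")
    big_k = knots[-1]

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - big_k, 0, None) ** 3
        return num / (big_k - knots[k])

    cols = [x]
    for k in range(len(knots) - 2):
        cols.append(d(k) - d(len(knots) - 2))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Samples x columns design with column roles and the formula used."""

    matrix: pd.DataFrame
    roles: dict[str, str]  # column -> {genotype, genotype:sex, spline}
    formula: str

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError("design matrix is column-rank deficient")

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    def drop_role(self, role_prefix: str) -> "DesignMatrix":
        keep = [c for c, r in self.roles.items() if not r.startswith(role_prefix)]
        return DesignMatrix(
            self.matrix[keep],
            {c: self.roles[c] for c in keep},
            self.formula + f" [minus {role_prefix}]",
        )


def build_design(
    meta: pd.DataFrame,
    preset: str = "fgo",
    spline_df: int = 3,
    covariate_override: pd.Series | None = None,
) -> DesignMatrix:
    """Design matrix for one of the study's three model presets.

    ``fgo``: ~ 0 + genotype. ``go_diameter``: ~ 0 + genotype + ns(d, 3).
    ``twocell_pseudotime_sex``: ~ 0 + genotype:sex + ns(PsT, 3).
    ``covariate_override`` replaces the continuous covariate values
    (used by the shuffled-covariate control).
    """
    cols = {}
    roles = {}
    if preset in ("fgo", "go_diameter"):
        for g in pd.unique(meta["genotype"]):
            cols[f"genotype[{g}]"] = (meta["genotype"] == g).astype(float)
            roles[f"genotype[{g}]"] = "genotype"
        formula = "~ 0 + genotype"
        if preset == "go_diameter":
            d = covariate_override if covariate_override is not None else meta["diameter"]
            basis = spline_basis(d.to_numpy(dtype=float), df=spline_df)
            for i in range(basis.shape[1]):
                cols[f"ns(d,{spline_df})[{i}]"] = basis[:, i]
                roles[f"ns(d,{spline_df})[{i}]"] = "spline"
            formula = f"~ 0 + genotype + ns(d,{spline_df})"
    elif preset == "twocell_pseudotime_sex":
        for g in pd.unique(meta["genotype"]):
            for s in pd.unique(meta["sex"]):
                key = f"genotype[{g}]:sex[{s}]"
                mask = (meta["genotype"] == g) & (meta["sex"] == s)
                if mask.any():
                    cols[key] = mask.astype(float)
                    roles[key] = "genotype:sex"
        pst = covariate_override if covariate_override is not None else meta["pseudotime"]
        basis = spline_basis(pst.to_numpy(dtype=float), df=spline_df)
        for i in range(basis.shape[1]):
            cols[f"ns(PsT,{spline_df})[{i}]"] = basis[:, i]
            roles[f"ns(PsT,{spline_df})[{i}]"] = "spline"
        formula = f"~ 0 + genotype:sex + ns(PsT,{spline_df})"
    else:
        raise ValueError(f"unknown design preset {preset!r}")
    matrix = pd.DataFrame(cols, index=meta.index)
    return DesignMatrix(matrix, roles, formula)


def contrast_vector(design: DesignMatrix, test: str, ctrl: str) -> np.ndarray:
    """Contrast of genotype coefficients: test - ctrl.

    For genotype:sex designs the sex-specific coefficients of each
    genotype are averaged before differencing (sex-averaged contrast).
    """
    c = np.zeros(design.n_params)
    cols = list(design.matrix.columns)
    for geno, sign in ((test, 1.0), (ctrl, -1.0)):
        idx = [
            i for i, name in enumerate(cols)
            if design.roles[name].startswith("genotype")
            and name.startswith(f"genotype[{geno}]")
        ]
        if not idx:
            raise ValueError(f"genotype {geno!r} not in design")
        for i in idx:
            c[i] = sign / len(idx)
    return c


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(
    table: CountTable, prior_weight: float = 30.0, floor: float = 1e-4
) -> pd.Series:
    """Per-gene NB dispersion, moment-based and shrunk to the cohort mean.

    Within each genotype group, counts are depth-normalized and the excess
    of their variance over the Poisson expectation gives a
    method-of-moments dispersion; group estimates are pooled by degrees of
    freedom and each gene's estimate is shrunk toward the mean of the
    positive raw estimates with ``prior_weight`` pseudo-samples. The heavy
    shrinkage is a deliberate empirical-Bayes stabilizer for the
    ~10-sample single-oocyte cohorts this model targets: per-gene moment
    estimates at n = 12 are far too noisy to plug in unshrunk, and an
    underestimated dispersion directly inflates the type-I error of the
    likelihood-ratio test. The mean (not median) target avoids the
    downward bias the median of a right-skewed estimator carries.
    """
    libsize = table.library_sizes().astype(float)
    s = libsize / np.exp(np.log(libsize).mean())
    z = table.counts.div(s, axis=1)
    groups = table.meta.groupby("genotype").groups
    num = pd.Series(0.0, index=table.region_ids)
    den = 0.0
    for _, libs in groups.items():
        if len(libs) < 2:
            continue
        zz = z[list(libs)]
        m = zz.mean(axis=1)
        v = zz.var(axis=1, ddof=1)
        poisson_var = m * float((1.0 / s[list(libs)]).mean())
        # E[m^2] = mu^2 + var(m): subtract var(m) ~ v/n so the denominator
        # estimates mu^2 rather than overshooting it (which deflates alpha)
        denom = (m.pow(2) - v / len(libs)).clip(lower=1e-12)
        a = (v - poisson_var) / denom
        a = a.replace([np.inf, -np.inf], np.nan).fillna(0.0).clip(lower=0.0)
        num += a * (len(libs) - 1)
        den += len(libs) - 1
    raw = num / max(den, 1.0)
    target = float(raw[raw > 0].mean()) if (raw > 0).any() else floor
    n_eff = den
    shrunk = (raw * n_eff + target * prior_weight) / (n_eff + prior_weight)
    return shrunk.clip(lower=floor)


# ---------------------------------------------------------------------------
# results container


@dataclass
class DEResults:
    """Per-gene differential-expression estimates and the test audit."""

    table: pd.DataFrame  # gene x {log2fc, pvalue, padj, mean_expr, converged}
    contrast: str
    design_formula: str
    lfc_thresh: float = DE_LFC_THRESH
    alpha: float = DE_ALPHA
    n_samples: int = 0

    def de_genes(self, direction: str = "both") -> pd.Index:
        t = self.table
        mask = (t["padj"] < self.alpha) & (t["log2fc"].abs() > self.lfc_thresh)
        if direction == "up":
            mask &= t["log2fc"] > 0
        elif direction == "down":
            mask &= t["log2fc"] < 0
        return t.index[mask.fillna(False)]

    @property
    def n_up(self) -> int:
        return len(self.de_genes("up"))

    @property
    def n_down(self) -> int:
        return len(self.de_genes("down"))

    def summary(self) -> str:
        t = self.table
        lines = [
            "Negative-binomial GLM differential expression",
            f"  design:   {self.design_formula}",
            f"  contrast: {self.contrast}",
            f"  genes tested: {len(t)}  samples: {self.n_samples}",
            f"  converged: {int(t['converged'].sum())}",
            f"  DE calls (|log2FC| > {self.lfc_thresh}, padj < {self.alpha}): "
            f"{self.n_up} up, {self.n_down} down",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# the model


class DifferentialExpressionModel:
    """NB GLM differential-expression model over a filtered count table.

    Parameters
    ----------
    table:
        Count table with genotype (and, per preset, diameter / pseudotime
        / sex) metadata. Genes should already satisfy the expression
        filter; :func:`filter_expressed` is applied on construction when
        ``prefilter`` is true.
    preset:
        Design preset (see :func:`build_design`).
    """

    def __init__(
        self,
        table: CountTable,
        preset: str = "fgo",
        spline_df: int = 3,
        prefilter: bool = True,
        min_cpm: float = 1.0,
        min_samples: int = 3,
        dispersion: pd.Series | None = None,
        covariate_override: pd.Series | None = None,
    ) -> None:
        if prefilter:
            table = filter_expressed(table, min_cpm, min_samples)
        self.table = table
        self.preset = preset
        self.spline_df = spline_df
        self.design = build_design(
            table.meta, preset, spline_df, covariate_override=covariate_override
        )
        self.dispersion = (
            dispersion if dispersion is not None else estimate_dispersions(table)
        )

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, meta: pd.DataFrame, **kw):
        return cls(CountTable(counts, meta), **kw)

    def fit(self, test: str, ctrl: str, maxiter: int = 100) -> DEResults:
        """Fit per-gene GLMs and test genotype with a likelihood-ratio test.

        ``test``/``ctrl`` name the genotype levels contrasted; for
        genotype:sex designs the contrast is sex-averaged.
        """
        cvec = contrast_vector(self.design, test, ctrl)
        xf = self.design.matrix.to_numpy(dtype=float)
        # constrained null model: columns spanning {X b : c'b = 0}
        xr = xf @ linalg.null_space(cvec.reshape(1, -1))
        return self._fit_with_designs(
            self.design, xr, cvec, f"{test} - {ctrl}", maxiter
        )

    def _fit_with_designs(self, full, reduced, cvec, contrast_name, maxiter=100):
        y_all = self.table.counts.to_numpy()
        xf = full.matrix.to_numpy(dtype=float)
        xr = reduced.matrix.to_numpy(dtype=float) if isinstance(
            reduced, DesignMatrix) else np.asarray(reduced, dtype=float)
        if xr.shape[1] >= xf.shape[1]:
            raise ValueError("reduced design must be nested in (smaller than) full")
        offset = np.log(self.table.library_sizes().to_numpy(dtype=float))
        df_diff = xf.shape[1] - xr.shape[1]
        alphas = self.dispersion.to_numpy()
        rows = []
        for gi, gene in enumerate(self.table.region_ids):
            y = y_all[gi]
            alpha = float(alphas[gi])
            try:
                fam = sm.families.NegativeBinomial(alpha=alpha)
                rf = sm.GLM(y, xf, family=fam, offset=offset).fit(maxiter=maxiter)
                rr = sm.GLM(y, xr, family=fam, offset=offset).fit(maxiter=maxiter)
                dev_diff = max(0.0, rr.deviance - rf.deviance)
                p = float(stats.chi2.sf(dev_diff, df_diff))
                lfc = float(cvec @ rf.params) / LN2
                rows.append((gene, lfc, p, float(y.mean()), True))
            except Exception:  # noqa: BLE001 - non-convergence is flagged per gene
                rows.append((gene, np.nan, np.nan, float(y.mean()), False))
        out = pd.DataFrame(
            rows, columns=["gene", "log2fc", "pvalue", "mean_expr", "converged"]
        ).set_index("gene")
        ok = out["pvalue"].notna()
        padj = pd.Series(np.nan, index=out.index)
        if ok.any():
            padj[ok] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
        out["padj"] = padj
        out = out[["log2fc", "pvalue", "padj", "mean_expr", "converged"]]
        return DEResults(
            out,
            contrast=contrast_name,
            design_formula=full.formula if isinstance(full, DesignMatrix) else "custom",
            n_samples=len(self.table.libraries),
        )

    def fit_shuffled(
        self, test: str, ctrl: str, covariate: str, seed: int = 0
    ) -> tuple[DEResults, DEResults, bool]:
        """Shuffled-covariate overfitting control.

        Reruns the identical pipeline with the continuous covariate
        permuted across samples. Returns (real, shuffled, overfit_flag);
        the flag is raised when the shuffled run yields more DE calls than
        real + max(5, 10% of real), i.e. when spline flexibility rather
        than the covariate drives calls.
        """
        real = self.fit(test, ctrl)
        rng = np.random.default_rng(seed)
        vals = self.table.meta[covariate].to_numpy(copy=True)
        shuffled = pd.Series(rng.permutation(vals), index=self.table.meta.index)
        alt = DifferentialExpressionModel(
            self.table,
            preset=self.preset,
            spline_df=self.spline_df,
            prefilter=False,
            dispersion=self.dispersion,
            covariate_override=shuffled,
        )
        shuf = alt.fit(test, ctrl)
        n_real = len(real.de_genes())
        n_shuf = len(shuf.de_genes())
        overfit = n_shuf > n_real + max(5, int(0.1 * n_real))
        return real, shuf, overfit


def fit_de_model(
    table: CountTable,
    design_full: DesignMatrix,
    design_reduced: DesignMatrix,
    contrast: np.ndarray,
    dispersion: pd.Series | None = None,
    contrast_name: str = "custom",
) -> DEResults:
    """Functional interface over explicit full/reduced designs."""
    model = DifferentialExpressionModel.__new__(DifferentialExpressionModel)
    model.table = table
    model.preset = "custom"
    model.spline_df = 0
    model.design = design_full
    model.design_reduced = design_reduced
    model.dispersion = (
        dispersion if dispersion is not None else estimate_dispersions(table)
    )
    return model._fit_with_designs(design_full, design_reduced, np.asarray(contrast),
                                   contrast_name)


# ---------------------------------------------------------------------------
# pseudotime and sex


def estimate_pseudotime(
    table: CountTable,
    exclude_genes=(),
    anchor_genes=(),
    psc: float = 0.1,
) -> pd.Series:
    """Sample ordering along the dominant expression trend, in [0, 1].

    A deliberately simple trajectory stand-in: rank of each sample on the
    first principal component of column-centred log2-CPM after removing
    excluded genes (sex chromosomes, imprinted genes), min-max scaled to
    [0, 1]. Orientation is fixed so pseudotime correlates positively with
    the mean expression of ``anchor_genes`` (e.g. known zygotic-activation
    genes); without anchors the orientation is arbitrary and a warning is
    emitted.
    """
    if len(table.libraries) < 4:
        raise ValueError("need >= 4 samples for pseudotime")
    keep = table.region_ids.difference(pd.Index(exclude_genes))
    sub = table.subset_regions(keep)
    lc = np.log2(cpm(sub) + psc)
    x = lc.to_numpy().T  # samples x genes
    xc = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    scores = xc @ vt[0]
    ranks = stats.rankdata(scores, method="average")
    if np.ptp(ranks) == 0:
        pst = np.full(len(ranks), 0.5)
    else:
        pst = (ranks - ranks.min()) / np.ptp(ranks)
    pst = pd.Series(pst, index=table.libraries, name="pseudotime")
    anchors = pd.Index(anchor_genes).intersection(table.region_ids)
    if len(anchors) == 0:
        logger.warning("estimate_pseudotime: no anchor genes; orientation arbitrary")
    else:
        anchor_expr = np.log2(cpm(table).loc[anchors] + psc).mean(axis=0)
        rho = stats.spearmanr(pst, anchor_expr).statistic
        if rho < 0:
            pst = 1.0 - pst
    return pst


def infer_sex(
    table: CountTable,
    chry_genes,
    chrx_genes,
    fold: float = 10.0,
    min_fraction: float = 1e-4,
) -> pd.Series:
    """Per-sample sex from the chrY read fraction.

    Samples are split into two groups by 2-means on the chrY read
    fraction; the female background is the median of the lower group and
    a sample is called M when its fraction exceeds ``fold`` times that
    background (with an absolute floor ``min_fraction``). High-group
    samples below the threshold are flagged ``ambiguous``. The decision
    audit (fractions, threshold) is attached to ``.attrs``.
    """
    chry_genes = pd.Index(chry_genes).intersection(table.region_ids)
    chrx_genes = pd.Index(chrx_genes).intersection(table.region_ids)
    if len(chry_genes) == 0 or len(chrx_genes) == 0:
        raise ValueError("need non-empty chrX and chrY gene sets")
    total = table.library_sizes().astype(float)
    y_frac = table.counts.loc[chry_genes].sum(axis=0) / total
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
        y_frac.to_numpy().reshape(-1, 1)
    )
    low_label = int(np.argmin(km.cluster_centers_.ravel()))
    female_bg = float(np.median(y_frac[km.labels_ == low_label]))
    threshold = max(fold * female_bg, min_fraction)
    calls = []
    for lib in table.libraries:
        in_high = km.labels_[list(table.libraries).index(lib)] != low_label
        if y_frac[lib] > threshold:
            calls.append("M")
        elif in_high:
            calls.append("ambiguous")
        else:
            calls.append("F")
    out = pd.Series(calls, index=table.libraries, name="sex")
    out.attrs["chry_fraction"] = y_frac
    out.attrs["threshold"] = threshold
    return out
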