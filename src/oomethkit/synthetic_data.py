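"""Synthetic-data generator with planted ground truth.

Emulates, post-alignment, the data structure of a hybrid mouse
oocyte/embryo epigenomics study: an annotation of genes, CpG islands and
intergenic tiles; a latent "true" epigenome per genotype in which
Polycomb-marked (PRC1) CGIs are unmethylated in control oocytes and gain
H3K36me2 and DNA methylation in Kdm2a/Kdm2b mutants wherever H2AK119u1
was present and H3K4me3 is low; and the assay-level observations (RNA-seq
counts, CUT&RUN fragment counts, WGBS methylation calls, hybrid-read
mismatch tables) with realistic distortions — library depth, uniform
background, bisulfite conversion failure, diameter/pseudotime
confounding, and strain SNPs.

Every generator is a pure function of its parameters and seed, and every
simulated object carries its ground-truth labels so downstream modules
have recovery targets.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from oomethkit.core_io import CpGIsland, Gene, GenomeAnnotation, GenomicInterval
from oomethkit.quantify import CountTable

logger = logging.getLogger(__name__)

GENOTYPES = ("ctrl", "aKO_bKO", "aKO_bdCxxC", "bdCxxC")

#: per-genotype latent modifiers: (residual H2AK119u1 multiplier,
#: H3K36me2 gain strength at permissive PRC1 targets, derepression
#: fold-change of PRC1-target gene expression)
GENOTYPE_EFFECTS: dict[str, tuple[float, float, float]] = {
    "ctrl": (1.0, 0.0, 1.0),
    "aKO_bKO": (0.02, 1.0, 4.0),
    "aKO_bdCxxC": (0.1, 0.8, 4.0),
    "bdCxxC": (0.3, 0.3, 2.0),
}

CLUSTER_LABELS = ("PRC1-CGI", "transcribed-CGI", "inactive", "intergenic")

#: fraction of intergenic tile bins with no specific signal at all
EMPTY_TILE_FRAC = 0.25


@dataclass(frozen=True)
class EffectParams:
    """Planted coefficients of the generative methylation model.

    True methylation obeys, on enrichment units rescaled by
    ``mark_scale``::

        meth = clamp(beta0 + b_k36me2*x2 + b_k36me3*x3 - b_k4me3*x4 + eps, 0, 1)

    and the mutant rule adds H3K36me2 proportional to the control
    H2AK119u1 level above a floor, wherever H3K4me3 is below
    ``k4me3_low``::

        k36me2_mut = k36me2_ctrl
                     + gain * max(h2a_ctrl - h2a_floor, 0) * 1{k4me3_ctrl < k4me3_low}

    The floor keeps regions with only background H2AK119u1 (for example
    gene bodies of stably expressed genes) unchanged in mutants, which is
    what the stable-gene CUT&RUN normalization assumes.
    """

    beta0: float = 0.02
    beta_k36me2: float = 0.6
    beta_k36me3: float = 0.3
    beta_k4me3: float = 0.2  # enters with a negative sign
    noise_sd: float = 0.02
    mark_scale: float = 10.0
    k4me3_low: float = 2.0  # enrichment units
    h2a_floor: float = 1.0  # enrichment units

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta_k36me2, self.beta_k36me3, -self.beta_k4me3])


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library's nuisance parameters and metadata."""

    genotype: str = "ctrl"
    depth: float = 1e6
    background_rate: float = 0.2
    conversion_failure: float = 0.005
    coverage: float = 10.0  # mean per-CpG WGBS coverage
    diameter: float | None = None  # oocyte diameter, um
    pseudotime: float | None = None  # embryo staging in [0, 1]
    sex: str | None = None
    replicate: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for name in ("background_rate", "conversion_failure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TrueEpigenome:
    """Latent per-region truth for one genotype.

    ``regions`` columns: region_id, kind {cgi, genebody, tile_bin}, chrom,
    start, end, cluster_label, h3k4me3, h3k36me2, h3k36me3, h2ak119u1,
    h3k27me3, meth_frac, expr_rate. ``params`` are the planted
    coefficients, ``n_clamped`` the number of regions where the linear
    methylation model had to be clamped into [0, 1].
    """

    genotype: str
    regions: pd.DataFrame
    params: EffectParams
    n_clamped: int = 0
    gene_expr: pd.DataFrame | None = None  # per-gene expr_rate + truth labels

    def marks_normalized(self) -> pd.DataFrame:
        cols = ["h3k36me2", "h3k36me3", "h3k4me3"]
        return self.regions[cols] / self.params.mark_scale


# ---------------------------------------------------------------------------
# annotation


def _cgi_sequence(rng: np.random.Generator, length: int, density: float) -> str:
    """Random sequence with approximately `density` CCG+CGG per 100 bp.

    Motifs are planted explicitly; background bases are rejected whenever
    they would complete a CCG/CGG trinucleotide, so density 0 yields
    exactly zero occurrences.
    """
    target = density * length / 100.0
    p_motif = min(1.0, target / max(1, length / 3.0) / 3.0 * 3.0)
    seq: list[str] = []
    bases = "ACGT"
    n_planted = 0
    while len(seq) < length:
        room = length - len(seq)
        if room >= 3 and n_planted < target and rng.random() < p_motif:
            seq.extend(rng.choice(["CCG", "CGG"]))
            n_planted += 1
            continue
        for _ in range(20):
            b = bases[rng.integers(4)]
            tail = "".join(seq[-2:]) + b
            if tail.endswith(("CCG", "CGG")):
                continue
            seq.append(b)
            break
        else:
            seq.append("A")
    return "".join(seq[:length])


def simulate_annotation(
    n_genes: int = 60,
    n_cgis: int = 80,
    n_tiles: int = 10,
    trinuc_spectrum: tuple[float, float] = (0.5, 4.0),
    seed: int = 0,
    gene_len_range: tuple[int, int] = (6_000, 70_000),
    cgi_width_range: tuple[int, int] = (300, 1_200),
    tile_width: int = 10_000,
    n_sex_genes: int = 5,
    max_retries: int = 1_000,
) -> GenomeAnnotation:
    """Generate a small genome annotation with planted structure.

    Genes (5-80 kb with exonic lengths) are placed without overlap on
    chr1; intergenic 10-kb tiles on chr2 (each later cut into 20 x 500 bp
    bins); CGIs sit at a subset of gene promoters, inside some gene
    bodies, and in intergenic space, and carry generated sequences whose
    CCG/CGG density is drawn from ``trinuc_spectrum``. ``n_sex_genes``
    genes each are added on chrX and chrY for sex inference.
    """
    if min(n_genes, n_cgis, n_tiles) < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    placed: list[tuple[int, int]] = []
    chrom_len = int(n_genes * (np.mean(gene_len_range) + 30_000) * 1.5)
    for i in range(n_genes):
        for attempt in range(max_retries):
            length = int(rng.integers(*gene_len_range))
            start = int(rng.integers(10_000, chrom_len - length - 10_000))
            if all(start + length + 2_000 < s or e + 2_000 < start for s, e in placed):
                break
        else:
            raise RuntimeError("could not place non-overlapping genes; enlarge genome")
        placed.append((start, start + length))
        exonic = int(length * rng.uniform(0.3, 0.9))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene("chr1", start, start + length, strand=strand, id=f"gene{i}",
                 exonic_length=exonic)
        )
    sex_genes: list[Gene] = []
    for chrom in (["chrX"] * n_sex_genes + ["chrY"] * n_sex_genes):
        i = len(sex_genes)
        start = 10_000 + i * 100_000
        length = int(rng.integers(8_000, 30_000))
        sex_genes.append(
            Gene(chrom, start, start + length, strand="+", id=f"{chrom}_gene{i}",
                 exonic_length=int(length * 0.5))
        )
    genes.extend(sex_genes)

    # CGIs: promoters of ~60% of autosomal genes first, rest intragenic/intergenic
    cgis: list[CpGIsland] = []
    auto = [g for g in genes if g.chrom == "chr1"]
    rng.shuffle(auto)
    n_promoter = min(int(0.6 * n_cgis), len(auto))
    new_genes = []
    promoter_gene_ids = set()
    for j in range(n_cgis):
        width = int(rng.integers(*cgi_width_range))
        density = float(rng.uniform(*trinuc_spectrum))
        if j < n_promoter:
            g = auto[j]
            mid = g.tss
            start = max(0, mid - width // 2)
            cid = f"cgi_prom_{g.id}"
            promoter_gene_ids.add(g.id)
        elif j < n_promoter + int(0.2 * n_cgis) and len(auto) > 0:
            g = auto[j % len(auto)]
            start = g.midpoint - width // 2
            cid = f"cgi_gb_{g.id}_{j}"
        else:
            start = int(rng.integers(10_000, chrom_len - width))
            cid = f"cgi_inter_{j}"
        seq = _cgi_sequence(rng, width, density)
        cgis.append(CpGIsland("chr1", start, start + width, id=cid, sequence=seq))
    for g in genes:
        cls = "CGI" if g.id in promoter_gene_ids else "non-CGI"
        new_genes.append(replace(g, promoter_class=cls))

    tiles = [
        GenomicInterval("chr2", 10_000 + i * (tile_width + 5_000),
                        10_000 + i * (tile_width + 5_000) + tile_width,
                        id=f"tile{i}")
        for i in range(n_tiles)
    ]
    chrom_sizes = {
        "chr1": chrom_len,
        "chr2": 10_000 + n_tiles * (tile_width + 5_000) + 10_000,
        "chrX": 10_000 + n_sex_genes * 100_000 + 50_000,
        "chrY": 10_000 + n_sex_genes * 100_000 + 50_000,
    }
    return GenomeAnnotation(new_genes, cgis, tiles, chrom_sizes)


# ---------------------------------------------------------------------------
# latent truth


def _baseline_marks(annotation: GenomeAnnotation, seed: int) -> pd.DataFrame:
    """Control-genotype latent marks; deterministic in (annotation, seed).

    Class archetypes (enrichment units, lognormal within-class spread):
    PRC1 CGIs carry high H2AK119u1/H3K27me3 with H3K4me3 spread across the
    permissive threshold (so in mutants some but not all PRC1 targets gain
    H3K36me2); transcribed (intragenic, transcription-coupled) regions
    carry high H3K36me2/me3 and are methylated already in control;
    inactive regions are low in everything.
    """
    rng = np.random.default_rng(seed)
    rows = []
    classes = ("PRC1-CGI", "transcribed-CGI", "inactive")
    probs = (0.4, 0.3, 0.3)

    def archetype(label: str, ln) -> dict:
        if label == "PRC1-CGI":
            return dict(h3k4me3=ln(1.0, 0.6), h3k36me2=ln(0.3), h3k36me3=ln(0.3),
                        h2ak119u1=ln(8.0), h3k27me3=ln(7.0))
        if label == "transcribed-CGI":
            # H3K4me3 spans a wide range at transcribed CGIs (promoter-
            # proximal vs body-internal islands), making it an
            # identifiable negative predictor of methylation
            return dict(h3k4me3=ln(2.2, 0.6), h3k36me2=ln(5.0, 0.3),
                        h3k36me3=ln(8.0, 0.2), h2ak119u1=ln(0.4), h3k27me3=ln(0.4))
        return dict(h3k4me3=ln(0.8, 0.5), h3k36me2=ln(0.8, 0.5),
                    h3k36me3=ln(0.6, 0.5), h2ak119u1=ln(0.6), h3k27me3=ln(0.8))

    for c in annotation.cgis:
        label = classes[rng.choice(3, p=probs)]
        ln = lambda m, s=0.15: float(m * rng.lognormal(0.0, s))
        rows.append(dict(region_id=c.id, kind="cgi", chrom=c.chrom,
                         start=c.start, end=c.end, cluster_label=label,
                         **archetype(label, ln)))
    promoter_label = {
        r["region_id"]: r["cluster_label"] for r in rows
    }
    for g in annotation.genes:
        ln = lambda m, s=0.15: float(m * rng.lognormal(0.0, s))
        # gene-body marks follow the promoter class
        label = promoter_label.get(f"cgi_prom_{g.id}", "inactive")
        rows.append(dict(region_id=f"gb_{g.id}", kind="genebody", chrom=g.chrom,
                         start=g.start, end=g.end, cluster_label=label,
                         **archetype(label, ln)))
    from oomethkit.core_io import make_windows

    # Intergenic tiles: a quarter are signal-free (detection-limit bins the
    # 15th-centile min-shift is meant to absorb); the rest carry modest
    # PRC1 presence, so mutants gain H3K36me2/DNAme in intergenic space.
    for b in make_windows(annotation, "tiles", tile_width=500):
        ln = lambda m, s=0.3: float(m * rng.lognormal(0.0, s))
        if rng.random() < EMPTY_TILE_FRAC:
            marks = dict(h3k4me3=0.0, h3k36me2=0.0, h3k36me3=0.0,
                         h2ak119u1=0.0, h3k27me3=0.0)
        else:
            marks = dict(h3k4me3=ln(0.3), h3k36me2=ln(1.0), h3k36me3=ln(0.8),
                         h2ak119u1=ln(3.0, 0.5), h3k27me3=ln(0.5))
        rows.append(dict(region_id=b.id, kind="tile_bin", chrom=b.chrom,
                         start=b.start, end=b.end, cluster_label="intergenic",
                         **marks))
    return pd.DataFrame(rows).set_index("region_id")


def simulate_truth(
    annotation: GenomeAnnotation,
    genotype: str = "ctrl",
    effect_params: EffectParams = EffectParams(),
    seed: int = 0,
) -> TrueEpigenome:
    """Latent epigenome for one genotype with the planted causal rules.

    The control baseline depends only on (annotation, seed), so truths for
    different genotypes generated with the same seed share it; genotype
    effects are then deterministic: H2AK119u1 is scaled by the residual
    multiplier, H3K36me2 gains proportionally to control H2AK119u1 where
    H3K4me3 is low, and methylation follows the planted linear model on
    the (possibly modified) marks. PRC1-target genes are derepressed by
    the genotype's expression fold-change.
    """
    if genotype not in GENOTYPE_EFFECTS:
        raise ValueError(f"unknown genotype {genotype!r}; known: {GENOTYPES}")
    base = _baseline_marks(annotation, seed)
    h2a_mult, gain, derepression = GENOTYPE_EFFECTS[genotype]
    regions = base.copy()
    permissive = base["h3k4me3"] < effect_params.k4me3_low
    h2a_above = (base["h2ak119u1"] - effect_params.h2a_floor).clip(lower=0.0)
    regions["h3k36me2"] = base["h3k36me2"] + gain * h2a_above * permissive
    regions["h2ak119u1"] = base["h2ak119u1"] * h2a_mult

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    x = regions[["h3k36me2", "h3k36me3", "h3k4me3"]].to_numpy() / effect_params.mark_scale
    eps = rng.normal(0.0, effect_params.noise_sd, size=len(regions))
    raw = effect_params.beta0 + x @ effect_params.betas + eps
    meth = np.clip(raw, 0.0, 1.0)
    n_clamped = int(((raw < 0) | (raw > 1)).sum())
    if n_clamped > 0.10 * len(regions):
        logger.warning(
            "simulate_truth: %d/%d regions clamped; planted-coefficient "
            "recovery will be distorted", n_clamped, len(regions),
        )
    regions["meth_frac"] = meth
    regions["clamped"] = (raw < 0) | (raw > 1)
    regions["permissive"] = permissive
    # planted methylome classes (from the generative rules, not observations)
    gains = permissive & (base["h2ak119u1"] > 3.0)
    regions["meth_class"] = np.where(
        regions["cluster_label"] == "transcribed-CGI", "methylated",
        np.where(gains, "gain-in-mutant", "unmethylated"),
    )

    # per-gene expression rates (transcripts per exonic bp, arbitrary units)
    gene_rows = {}
    for g in annotation.genes:
        label = regions.loc[f"gb_{g.id}", "cluster_label"]
        rng_g = np.random.default_rng(
            np.random.SeedSequence([seed, 11, zlib.crc32(g.id.encode())])
        )
        if label == "transcribed-CGI":
            rate = float(rng_g.lognormal(np.log(5.0), 0.4))
        elif label == "PRC1-CGI":
            rate = float(rng_g.lognormal(np.log(0.2), 0.3)) * derepression
        else:
            rate = float(rng_g.lognormal(np.log(1.0), 0.5))
        gene_rows[g.id] = dict(expr_rate=rate, cluster_label=label,
                               exonic_length=g.exonic_length, chrom=g.chrom,
                               derepressed=(label == "PRC1-CGI" and derepression > 1))
    gene_expr = pd.DataFrame.from_dict(gene_rows, orient="index")
    regions["expr_rate"] = 0.0
    for gid, row in gene_expr.iterrows():
        regions.loc[f"gb_{gid}", "expr_rate"] = row["expr_rate"]
    return TrueEpigenome(genotype, regions, effect_params, n_clamped, gene_expr)


# ---------------------------------------------------------------------------
# assay-level observations


def _diameter_modulation(diameter: float, loadings: np.ndarray,
                         d_range: tuple[float, float] = (55.0, 80.0)) -> np.ndarray:
    """Per-gene multiplicative factor: loading x cubic smooth of diameter."""
    lo, hi = d_range
    t = 2.0 * (diameter - lo) / (hi - lo) - 1.0
    return np.exp(loadings * t**3)


def simulate_counts(
    truth: TrueEpigenome,
    windows,
    assay: str,
    spec: LibrarySpec,
    dispersion_range: tuple[float, float] = (0.05, 0.4),
    diameter_loading_sd: float = 0.5,
) -> CountTable:
    """One library of RNA-seq or CUT&RUN counts over the given windows.

    RNA-seq windows must be genes of the truth's annotation: expected
    counts follow expr_rate x exonic length, negative-binomially dispersed
    (per-gene dispersion drawn once from ``dispersion_range`` using the
    truth seed's stream), and modulated by a per-gene loading times a
    cubic smooth of oocyte diameter when the spec carries one — so
    unbalanced diameters confound genotype. CUT&RUN windows take Poisson
    counts from enrichment x width plus a uniform (width-proportional)
    background at ``spec.background_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    if assay == "rnaseq":
        genes = truth.gene_expr
        ids = [w.id for w in windows]
        sub = genes.loc[ids]
        rate = (sub["expr_rate"] * sub["exonic_length"]).to_numpy(dtype=float)
        # reproducible per-gene nuisance parameters, shared across libraries
        nuisance = np.random.default_rng(zlib.crc32("|".join(ids).encode()))
        dispersion = nuisance.uniform(*dispersion_range, size=len(ids))
        loadings = nuisance.normal(0.0, diameter_loading_sd, size=len(ids))
        if spec.diameter is not None:
            rate = rate * _diameter_modulation(spec.diameter, loadings)
        if rate.sum() == 0:
            raise ValueError("zero total rate")
        mu = spec.depth * rate / rate.sum()
        # NB via gamma-Poisson mixture
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
        counts = rng.poisson(lam)
        meta = _meta_frame(spec)
        return CountTable(
            pd.DataFrame({meta.index[0]: counts}, index=ids),
            meta,
            region_lengths=sub["exonic_length"].astype(float),
            extras={
                "dispersion": pd.Series(dispersion, index=ids),
                "diameter_loadings": pd.Series(loadings, index=ids),
            },
        )
    if assay == "cutrun":
        raise ValueError("use simulate_cutrun_counts with an explicit mark")
    raise ValueError(f"unknown assay {assay!r}")


def simulate_cutrun_counts(
    truth: TrueEpigenome, windows, mark: str, spec: LibrarySpec,
    genome_size: float | None = None,
) -> CountTable:
    """CUT&RUN fragment counts for one mark over truth regions.

    Window ids must be region ids of the truth table. Expected counts mix
    specific signal (enrichment x width) with uniform background at
    ``spec.background_rate``; counts are Poisson. Background fragments
    fall uniformly over ``genome_size`` bp (so most of them land outside
    the counted windows, as in real data); when ``genome_size`` is None
    the background is spread over the windows alone.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [w.id for w in windows]
    widths = np.array([w.width for w in windows], dtype=float)
    enr = truth.regions.loc[ids, mark].to_numpy(dtype=float)
    signal = enr * widths
    if signal.sum() == 0 and spec.background_rate == 0:
        raise ValueError("zero total rate")
    p_sig = signal / signal.sum() if signal.sum() > 0 else np.zeros_like(signal)
    bg_span = float(genome_size) if genome_size else widths.sum()
    p_bg = widths / bg_span
    p = (1.0 - spec.background_rate) * p_sig + spec.background_rate * p_bg
    counts = rng.poisson(spec.depth * p)
    meta = _meta_frame(spec)
    return CountTable(pd.DataFrame({meta.index[0]: counts}, index=ids), meta)


def _meta_frame(spec: LibrarySpec) -> pd.DataFrame:
    name = f"{spec.genotype}_r{spec.replicate}_s{spec.seed}"
    return pd.DataFrame(
        {
            "genotype": [spec.genotype],
            "depth": [spec.depth],
            "diameter": [spec.diameter],
            "pseudotime": [spec.pseudotime],
            "sex": [spec.sex],
            "replicate": [spec.replicate],
        },
        index=pd.Index([name], name="library"),
    )


def combine_libraries(tables: list[CountTable]) -> CountTable:
    """Column-bind single-library tables on their shared region index."""
    counts = pd.concat([t.counts for t in tables], axis=1)
    meta = pd.concat([t.meta for t in tables], axis=0)
    lengths = tables[0].region_lengths
    return CountTable(counts.fillna(0).astype(int), meta, lengths,
                      extras=dict(tables[0].extras))


def simulate_expression_matrix(
    genotypes: list[str],
    n_genes: int = 2_000,
    depth: float = 1e6,
    dispersion: float = 0.1,
    n_de: int = 0,
    log2fc: float = 0.0,
    covariate: np.ndarray | None = None,
    covariate_frac: float = 0.0,
    covariate_strength: float = 1.0,
    seed: int = 0,
) -> CountTable:
    """Direct NB count matrix for differential-expression calibration runs.

    One column per entry of ``genotypes``; gene base abundances are
    lognormal. The first ``n_de`` genes carry ``log2fc`` in every
    non-control genotype (controls are the first genotype label). When a
    per-sample ``covariate`` is given (diameter- or pseudotime-like, any
    scale), a random ``covariate_frac`` of genes responds to its cubic
    smooth with per-gene loadings of SD ``covariate_strength`` — planting
    the confounding that the spline adjustment is meant to absorb.
    Ground truth (DE flags, loadings) is stored in ``extras``.
    """
    rng = np.random.default_rng(seed)
    n_samples = len(genotypes)
    base = rng.lognormal(np.log(50.0), 1.0, size=n_genes)
    genes = [f"g{i}" for i in range(n_genes)]
    ctrl = genotypes[0]
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[:n_de] = True
    responds = np.zeros(n_genes, dtype=bool)
    loadings = np.zeros(n_genes)
    if covariate is not None and covariate_frac > 0:
        responds = rng.random(n_genes) < covariate_frac
        loadings[responds] = rng.normal(0.0, covariate_strength,
                                        size=int(responds.sum()))
        c = np.asarray(covariate, dtype=float)
        t = 2.0 * (c - c.min()) / max(np.ptp(c), 1e-12) - 1.0
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j, g in enumerate(genotypes):
        mu = base.copy()
        if g != ctrl:
            mu[is_de] *= 2.0**log2fc
        if covariate is not None and covariate_frac > 0:
            mu = mu * np.exp(loadings * t[j] ** 3)
        mu = depth * mu / mu.sum()
        lam = rng.gamma(1.0 / dispersion, mu * dispersion)
        counts[:, j] = rng.poisson(lam)
    meta = pd.DataFrame(
        {
            "genotype": genotypes,
            "depth": depth,
            "diameter": covariate if covariate is not None else np.nan,
            "pseudotime": covariate if covariate is not None else np.nan,
            "sex": None,
            "replicate": np.arange(1, n_samples + 1),
        },
        index=pd.Index([f"s{j}" for j in range(n_samples)], name="library"),
    )
    table = CountTable(pd.DataFrame(counts, index=genes, columns=meta.index), meta)
    table.extras["is_de"] = pd.Series(is_de, index=genes)
    table.extras["covariate_loadings"] = pd.Series(loadings, index=genes)
    return table


def simulate_wgbs(
    truth: TrueEpigenome,
    spec: LibrarySpec,
    n_cpg_per_region: int = 10,
    n_chh_sites: int = 2_000,
    haplotype: str | None = None,
    region_kinds: tuple[str, ...] = ("cgi", "genebody", "tile_bin"),
):
    """Per-CpG methylation calls for one WGBS library.

    Each truth region receives ``n_cpg_per_region`` CpG sites at uniform
    positions; coverage is Poisson(spec.coverage) and methylated counts
    are Binomial(coverage, m + (1-m) * conversion_failure), so failed
    bisulfite conversion inflates apparent methylation. ``n_chh_sites``
    non-CpG sites with true methylation 0 estimate the conversion-failure
    rate. Zero-coverage sites are emitted with total 0.
    """
    from oomethkit.methylome import MethCallTable

    rng = np.random.default_rng(spec.seed)
    cf = spec.conversion_failure
    sub = truth.regions[truth.regions["kind"].isin(region_kinds)]
    n = len(sub)
    rows = []
    for (rid, r) in sub.iterrows():
        # CpG positions are genomic features: identical across libraries
        pos_rng = np.random.default_rng(
            np.random.SeedSequence([zlib.crc32(str(rid).encode()), 13])
        )
        pos = np.sort(pos_rng.integers(r["start"], r["end"], size=n_cpg_per_region))
        cov = rng.poisson(spec.coverage, size=n_cpg_per_region)
        p_obs = r["meth_frac"] + (1.0 - r["meth_frac"]) * cf
        meth = rng.binomial(cov, p_obs)
        for pp, cc, mm in zip(pos, cov, meth):
            rows.append((r["chrom"], int(pp), "CpG", int(mm), int(cc)))
    chroms = sub["chrom"].unique()
    for i in range(n_chh_sites):
        cov = rng.poisson(spec.coverage)
        meth = rng.binomial(cov, cf)
        ctx = "CHH" if i % 2 == 0 else "CHG"
        rows.append((chroms[i % len(chroms)], 1 + i, ctx, int(meth), int(cov)))
    calls = pd.DataFrame(
        rows, columns=["chrom", "pos", "context", "methylated", "total"]
    )
    if haplotype is not None:
        calls["haplotype"] = haplotype
    name = f"wgbs_{spec.genotype}_r{spec.replicate}_s{spec.seed}"
    return MethCallTable(calls, total_reads=int(spec.depth), name=name)


def simulate_hybrid_reads(
    n_reads: int,
    origin_fracs: tuple[float, float] = (0.45, 0.45),
    snps_per_read: tuple[str, float] = ("poisson", 2.0),
    error_rate: float = 0.0,
    seed: int = 0,
    feature_ids: list[str] | None = None,
):
    """Reads with mismatch counts against the two parental genomes.

    ``origin_fracs = (maternal, paternal)`` must sum to <= 1; the
    remainder are reads covering no SNP (0 mismatches to both genomes,
    hence undefined downstream). SNP-covering reads draw k >= 1 SNPs from
    the given distribution ("poisson", lam: zero-truncated; or ("fixed",
    k)). Sequencing errors at SNP positions flip mismatches between the
    genomes: with e ~ Binomial(k, error_rate), a maternal read shows
    (e, k - e). Reads are mapped uniformly over ``feature_ids``.
    """
    from oomethkit.allelic import ReadMismatchTable

    fm, fp = origin_fracs
    if fm < 0 or fp < 0 or fm + fp > 1.0 + 1e-12:
        raise ValueError("origin_fracs must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    origin = rng.choice(
        ["maternal", "paternal", "none"], size=n_reads, p=[fm, fp, 1.0 - fm - fp]
    )
    kind, param = snps_per_read
    covering = origin != "none"
    k = np.zeros(n_reads, dtype=int)
    nc = int(covering.sum())
    if kind == "poisson":
        # zero-truncated Poisson: a SNP-covering read covers >= 1 SNP
        draw = rng.poisson(param, size=nc)
        while (draw == 0).any():
            zeros = draw == 0
            draw[zeros] = rng.poisson(param, size=int(zeros.sum()))
        k[covering] = draw
    elif kind == "fixed":
        k[covering] = int(param)
    else:
        raise ValueError(f"unknown snps_per_read distribution {kind!r}")
    e = rng.binomial(k, error_rate)
    mm_mat = np.where(origin == "maternal", e, np.where(origin == "paternal", k - e, 0))
    mm_pat = np.where(origin == "maternal", k - e, np.where(origin == "paternal", e, 0))
    if feature_ids is None:
        feature_ids = ["featureA"]
    features = np.asarray(feature_ids)[rng.integers(len(feature_ids), size=n_reads)]
    reads = pd.DataFrame(
        {
            "mismatches_maternal": mm_mat,
            "mismatches_paternal": mm_pat,
            "mapped_feature": features,
            "true_origin": origin,
        }
    )
    return ReadMismatchTable(reads)
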