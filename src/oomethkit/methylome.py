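"""WGBS methylation quantification, QC, MDS reproducibility and models.

Bisulfite sequencing reads unmethylated cytosines as thymines; failed
conversion therefore inflates apparent methylation. Because CHG/CHH
(non-CpG) methylation is essentially absent in oocytes, the observed
non-CpG methylation level of a library estimates its conversion-failure
rate and drives one of the QC filters. Sample reproducibility is judged by
classical MDS on Euclidean distances between per-tile methylation
profiles, and passing libraries of one genotype are merged by count
addition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from oomethkit.quantify import kmeans_cluster

logger = logging.getLogger(__name__)

CPG = "CpG"
NON_CPG = ("CHG", "CHH")


@dataclass
class MethCallTable:
    """Per-site methylation calls.

    ``calls`` columns: chrom, pos, context ({CpG, CHG, CHH}), methylated,
    total, and optionally haplotype ({maternal, paternal, untagged}).
    ``total_reads`` is the sequencing library size used by QC (not the sum
    of per-site coverages).
    """

    calls: pd.DataFrame
    total_reads: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        c = self.calls
        if ((c["methylated"] < 0) | (c["methylated"] > c["total"])).any():
            raise ValueError("need 0 <= methylated <= total at every site")

    def noncpg_methylation(self) -> float:
        """Pooled CHG+CHH methylation fraction (conversion-failure proxy)."""
        sub = self.calls[self.calls["context"].isin(NON_CPG)]
        tot = sub["total"].sum()
        if tot == 0:
            raise ValueError("no covered non-CpG sites")
        return float(sub["methylated"].sum() / tot)


def methylation_levels(calls: MethCallTable, regions) -> pd.Series:
    """Pooled per-region mCpG/CpG in percent.

    The estimator is 100 * sum(methylated) / sum(total) over CpG-context
    sites inside each region (read-weighted); regions without covered CpGs
    are NA. ``per_cpg_mean`` in :func:`methylation_levels_mean` gives the
    unweighted mean-of-CpG-means variant.
    """
    return _region_levels(calls, regions, pooled=True)


def methylation_levels_mean(calls: MethCallTable, regions) -> pd.Series:
    """Per-region mean of per-CpG methylation percentages (unweighted)."""
    return _region_levels(calls, regions, pooled=False)


def _region_levels(calls: MethCallTable, regions, pooled: bool) -> pd.Series:
    cpg = calls.calls[
        (calls.calls["context"] == CPG) & (calls.calls["total"] > 0)
    ]
    out = {}
    for r in regions:
        sub = cpg[
            (cpg["chrom"] == r.chrom)
            & (cpg["pos"] >= r.start)
            & (cpg["pos"] < r.end)
        ]
        if sub.empty or sub["total"].sum() == 0:
            out[r.id] = np.nan
        elif pooled:
            out[r.id] = 100.0 * sub["methylated"].sum() / sub["total"].sum()
        else:
            out[r.id] = float((100.0 * sub["methylated"] / sub["total"]).mean())
    return pd.Series(out, name="meth_pct")


@dataclass
class QCReport:
    passed: bool
    reasons: list[str]


def qc_libraries(
    libraries: list[MethCallTable],
    min_reads: float = 1e7,
    max_noncpg: float = 0.07,
    genotypes: list[str] | None = None,
    mds_outlier_k: float = 3.0,
    n_tiles: int = 100_000,
    tile_width: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """QC verdict per library with enumerated reasons.

    A library fails if its total read count is <= ``min_reads``, its
    pooled non-CpG methylation is >= ``max_noncpg``, or it is an MDS
    outlier among its genotype peers (median distance > k x MAD above the
    cohort; see :func:`tile_mds`). Returns a DataFrame indexed by library
    name with columns pass/reasons/library_reads/noncpg.
    """
    rows = {}
    fail_reasons: dict[str, list[str]] = {}
    for lib in libraries:
        reasons = []
        if lib.total_reads <= min_reads:
            reasons.append(f"library size {lib.total_reads:.3g} <= {min_reads:.3g}")
        noncpg = lib.noncpg_methylation()
        if noncpg >= max_noncpg:
            reasons.append(
                f"non-CpG methylation {100 * noncpg:.1f}% >= {100 * max_noncpg:.0f}%"
            )
        fail_reasons[lib.name] = reasons
        rows[lib.name] = {"library_reads": lib.total_reads, "noncpg": noncpg}
    if len(libraries) >= 3:
        try:
            _, outliers = tile_mds(
                libraries,
                n_tiles=n_tiles,
                tile_width=tile_width,
                seed=seed,
                genotypes=genotypes,
                outlier_k=mds_outlier_k,
            )
            for name, is_out in outliers.items():
                if is_out:
                    fail_reasons[name].append("tile-MDS outlier")
        except ValueError as exc:
            logger.warning("qc_libraries: MDS skipped (%s)", exc)
    report = pd.DataFrame.from_dict(rows, orient="index")
    report["pass"] = [not fail_reasons[n] for n in report.index]
    report["reasons"] = ["; ".join(fail_reasons[n]) for n in report.index]
    return report


def classical_mds(dist: np.ndarray, n_components: int = 2):
    """Torgerson classical MDS of a distance matrix.

    Double-centres the squared distances and eigendecomposes; returns
    (coordinates, strain) where strain is the summed magnitude of negative
    eigenvalues (0 when the points embed exactly in ``n_components``
    dimensions, in which case the embedding reproduces the distances).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    strain = float(np.abs(w[w < 0]).sum() + np.abs(w[n_components:][w[n_components:] > 0]).sum())
    wpos = np.clip(w[:n_components], 0, None)
    coords = v[:, :n_components] * np.sqrt(wpos)
    return coords, strain


def tile_mds(
    libraries: list[MethCallTable],
    n_tiles: int = 100_000,
    tile_width: int = 500,
    seed: int = 0,
    genotypes: list[str] | None = None,
    outlier_k: float = 3.0,
):
    """2-D classical MDS of libraries from random-tile methylation profiles.

    Draws up to ``n_tiles`` random ``tile_width``-bp genomic tiles (scaled
    down automatically to what the genome offers), computes per-tile
    methylation per library, drops tiles with NA in any library, and
    embeds the pairwise Euclidean distance matrix. A library is flagged as
    an outlier when its median distance to same-genotype peers exceeds the
    cohort median by more than ``outlier_k`` x MAD of those medians.

    Returns (DataFrame with mds1/mds2 per library, outlier flags dict).
    """
    if len(libraries) < 3:
        raise ValueError("need >= 3 libraries for MDS QC")
    rng = np.random.default_rng(seed)
    # candidate tiles from the union of covered CpG positions
    pos_frames = []
    for lib in libraries:
        cpg = lib.calls[lib.calls["context"] == CPG]
        pos_frames.append(cpg[["chrom", "pos"]])
    all_pos = pd.concat(pos_frames).drop_duplicates()
    all_pos = all_pos.assign(tile=all_pos["pos"] // tile_width)
    tiles = all_pos[["chrom", "tile"]].drop_duplicates()
    n_use = min(n_tiles, len(tiles))
    if n_use < 3:
        raise ValueError("fewer than 3 usable tiles")
    take = tiles.iloc[rng.choice(len(tiles), size=n_use, replace=False)]
    key = pd.MultiIndex.from_frame(take)

    profiles = []
    for lib in libraries:
        cpg = lib.calls[(lib.calls["context"] == CPG) & (lib.calls["total"] > 0)]
        g = cpg.assign(tile=cpg["pos"] // tile_width).groupby(["chrom", "tile"])
        lev = 100.0 * g["methylated"].sum() / g["total"].sum()
        profiles.append(lev.reindex(key))
    mat = pd.concat(profiles, axis=1)
    mat.columns = [lib.name for lib in libraries]
    mat = mat.dropna(axis=0)
    if len(mat) < 3:
        raise ValueError("fewer than 3 usable tiles")
    x = mat.to_numpy().T  # libraries x tiles
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    coords, strain = classical_mds(dist, 2)
    emb = pd.DataFrame(coords, index=mat.columns, columns=["mds1", "mds2"])
    emb.attrs["strain"] = strain
    emb.attrs["distances"] = pd.DataFrame(dist, index=mat.columns, columns=mat.columns)

    if genotypes is None:
        genotypes = ["all"] * len(libraries)
    med = {}
    for i, lib in enumerate(libraries):
        peers = [
            j for j in range(len(libraries))
            if j != i and genotypes[j] == genotypes[i]
        ]
        med[lib.name] = float(np.median(dist[i, peers])) if peers else 0.0
    meds = np.array(list(med.values()))
    center = np.median(meds)
    mad = np.median(np.abs(meds - center))
    cutoff = center + outlier_k * max(mad, 1e-12)
    outliers = {name: bool(m > cutoff) for name, m in med.items()}
    return emb, outliers


def merge_genotype(libraries: list[MethCallTable], name: str = "merged") -> MethCallTable:
    """Merge passing libraries of one genotype by site-wise count addition."""
    if not libraries:
        raise ValueError("need at least one library to merge")
    frames = [
        lib.calls.set_index(["chrom", "pos", "context"])[["methylated", "total"]]
        for lib in libraries
    ]
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.add(f, fill_value=0)
    merged = merged.astype(int).reset_index()
    return MethCallTable(
        merged,
        total_reads=sum(lib.total_reads for lib in libraries),
        name=name,
    )


def cluster_cgi_methylomes(
    levels: pd.DataFrame, k: int, seed: int = 0, n_starts: int = 100
) -> pd.Series:
    """k-means on raw CGI methylation percentages across conditions.

    Absolute (not z-scored) levels are clustered, so clusters reflect
    methylation magnitude. Rows with any NA are excluded and reported.
    Labels are canonicalized by descending mean methylation in the first
    condition column.
    """
    usable = levels.dropna(axis=0)
    dropped = len(levels) - len(usable)
    if dropped:
        logger.info("cluster_cgi_methylomes: dropped %d rows with NA", dropped)
    if usable.empty:
        raise ValueError("no usable rows (all contain NA)")
    labels, _ = kmeans_cluster(usable.to_numpy(), k=k, n_starts=n_starts, seed=seed)
    # canonicalize by descending mean of first condition
    first = usable.iloc[:, 0].to_numpy()
    means = np.array([first[labels == c].mean() for c in range(k)])
    order = np.argsort(-means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return pd.Series(relabel[labels], index=usable.index, name="cluster")


@dataclass
class DilutionModel:
    """Passive replication-dilution of DNA methylation.

    Each S phase, a methylated CpG keeps its mark on the parental strand;
    the daughter strand is methylated with probability
    ``maintenance_prob``. Under strand-symmetric accounting the expected
    methylation after one division is m * (1 + p) / 2: p = 1 conserves,
    p = 0 halves. ``post_replication`` adds one extra replication (S phase
    completed but division not yet) for cells sampled after DNA synthesis.
    """

    m0: float
    divisions: int
    maintenance_prob: float
    post_replication: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.m0 <= 1.0:
            raise ValueError("m0 must lie in [0, 1]")
        if not 0.0 <= self.maintenance_prob <= 1.0:
            raise ValueError("maintenance_prob must lie in [0, 1]")
        if self.divisions < 0:
            raise ValueError("divisions must be >= 0")


def passive_dilution(model: DilutionModel) -> tuple[float, float]:
    """Expected final methylation fraction and fold reduction m0/m_final."""
    per_round = (1.0 + model.maintenance_prob) / 2.0
    rounds = model.divisions + (1 if model.post_replication else 0)
    m_final = model.m0 * per_round**rounds
    fold = model.m0 / m_final if m_final > 0 else float("inf")
    return m_final, fold
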