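"""Window counting, expression normalization, metagene matrices and k-means.

The metagene layout follows the heatmap convention used for chromatin
profiles over genes: 10 fixed 500-bp windows upstream of the TSS, 20
variable-width windows spanning the gene body, and 10 fixed 500-bp windows
downstream of the TES, strand-oriented so column 1 is always the most 5'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from oomethkit.core_io import GenomeAnnotation, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Regions x libraries integer counts plus per-library metadata.

    ``meta`` is indexed by library name and may carry genotype, depth,
    diameter, pseudotime, sex and replicate columns as the assay needs.
    """

    counts: pd.DataFrame  # regions x libraries, non-negative integers
    meta: pd.DataFrame  # libraries x metadata
    region_lengths: pd.Series | None = None  # bp; exonic length for RNA-seq
    extras: dict = field(default_factory=dict)  # e.g. simulator ground truth

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not list(self.counts.columns) == list(self.meta.index):
            raise ValueError("count columns and metadata index must align")

    @property
    def region_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_regions(self, ids) -> "CountTable":
        lengths = None
        if self.region_lengths is not None:
            lengths = self.region_lengths.loc[ids]
        return CountTable(self.counts.loc[ids], self.meta, lengths, dict(self.extras))


@dataclass
class MetageneMatrix:
    """Genes x 40 window values (10 upstream, 20 body, 10 downstream)."""

    values: pd.DataFrame  # genes x 40
    flank_window_bp: int = 500
    excluded: dict[str, str] = field(default_factory=dict)  # gene -> reason

    def __post_init__(self) -> None:
        if self.values.shape[1] != 40:
            raise ValueError("metagene matrix must have exactly 40 columns")


def count_in_windows(fragments, windows) -> pd.Series:
    """Count fragments into windows by fragment midpoint.

    A fragment is counted in every window containing its midpoint, so
    counting is orientation-insensitive and each fragment contributes at
    most once per window. Returns a Series indexed by window id.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, i))
    # sort by start for a scan; windows may overlap so use interval checks
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    starts = {c: np.array([w[0] for w in v]) for c, v in by_chrom.items()}
    for frag in fragments:
        wins = by_chrom.get(frag.chrom)
        if wins is None:
            continue
        mid = frag.midpoint
        # candidate windows start at or before mid
        hi = int(np.searchsorted(starts[frag.chrom], mid, side="right"))
        for s, e, i in wins[:hi]:
            if s <= mid < e:
                counts[i] += 1
    ids = [w.id if w.id else str(k) for k, w in enumerate(windows)]
    return pd.Series(counts, index=ids, name="count")


def log_rpkm(table: CountTable, psc: float = 0.1) -> pd.DataFrame:
    """Reads per kb per million on the log2 scale with a pseudocount.

    RPKM normalizes each gene's exonic read count to the gene's total
    exonic length and the library's total exonic reads; the log transform
    is ``log2(RPKM + psc) - log2(psc)`` so a zero count maps to exactly 0.
    """
    if table.region_lengths is None:
        raise ValueError("region_lengths (exonic bp) required for RPKM")
    lengths = table.region_lengths.loc[table.region_ids].astype(float)
    if (lengths <= 0).any():
        raise ValueError("all region lengths must be positive")
    libsize = table.library_sizes().astype(float)
    if (libsize == 0).any():
        raise ValueError("zero library size")
    rpkm = table.counts.div(lengths / 1e3, axis=0).div(libsize / 1e6, axis=1)
    return np.log2(rpkm + psc) - np.log2(psc)


def cpm(table: CountTable) -> pd.DataFrame:
    libsize = table.library_sizes().astype(float)
    if (libsize == 0).any():
        raise ValueError("zero library size")
    return table.counts.div(libsize / 1e6, axis=1)


def _window_means(signal: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean of a per-bp signal between consecutive integer edges."""
    csum = np.concatenate([[0.0], np.cumsum(signal)])
    lo = edges[:-1]
    hi = edges[1:]
    widths = (hi - lo).astype(float)
    return (csum[hi] - csum[lo]) / widths


def metagene_matrix(
    annotation: GenomeAnnotation,
    signal: dict[str, np.ndarray],
    min_len: int = 5_000,
    max_len: int = 80_000,
    flank_bp: int = 5_000,
    n_flank_windows: int = 10,
    n_body_windows: int = 20,
) -> MetageneMatrix:
    """Per-gene 40-column window means of a per-bp signal.

    Genes with bodies outside (``min_len``, ``max_len``) are excluded with
    a recorded reason, as are genes whose span with flanks leaves the
    chromosome. Columns are strand-oriented (column 1 = most 5').
    """
    rows = {}
    excluded: dict[str, str] = {}
    fw = flank_bp // n_flank_windows
    for g in annotation.genes:
        body = g.width
        if not (min_len < body < max_len):
            excluded[g.id] = f"gene body {body} bp outside ({min_len}, {max_len})"
            continue
        if body < n_body_windows:
            excluded[g.id] = "gene body shorter than window count"
            continue
        chrom_signal = signal[g.chrom]
        lo = g.start - flank_bp
        hi = g.end + flank_bp
        if lo < 0 or hi > len(chrom_signal):
            excluded[g.id] = "flanked span exceeds chromosome bounds"
            continue
        up_edges = np.arange(lo, g.start + 1, fw)
        body_edges = np.unique(
            np.round(np.linspace(g.start, g.end, n_body_windows + 1)).astype(int)
        )
        if len(body_edges) != n_body_windows + 1:
            excluded[g.id] = "degenerate body windows"
            continue
        down_edges = np.arange(g.end, hi + 1, fw)
        vals = np.concatenate(
            [
                _window_means(chrom_signal, up_edges),
                _window_means(chrom_signal, body_edges),
                _window_means(chrom_signal, down_edges),
            ]
        )
        if g.strand == "-":
            vals = vals[::-1]
        rows[g.id] = vals
    if excluded:
        logger.info("metagene_matrix: excluded %d genes", len(excluded))
    columns = (
        [f"up{i}" for i in range(n_flank_windows)]
        + [f"body{i}" for i in range(n_body_windows)]
        + [f"down{i}" for i in range(n_flank_windows)]
    )
    values = pd.DataFrame.from_dict(rows, orient="index")
    if values.empty:
        values = pd.DataFrame(columns=columns, dtype=float)
    else:
        values.columns = columns
    return MetageneMatrix(values, flank_window_bp=fw, excluded=excluded)


def running_mean(row: np.ndarray, kernel: int) -> np.ndarray:
    """Centred running mean; the window shrinks at the row boundaries."""
    if kernel % 2 != 1:
        raise ValueError("kernel must be odd")
    n = len(row)
    if kernel > n:
        raise ValueError("kernel larger than row")
    half = kernel // 2
    csum = np.concatenate([[0.0], np.cumsum(row)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_and_scale(
    matrix: np.ndarray,
    kernel: int = 5,
    lo_hi_centiles: tuple[float, float] = (2.0, 98.0),
    zscore_rows: bool = False,
    zscore_before_smoothing: bool = True,
) -> np.ndarray:
    """Row-wise running-mean smoothing then global centile clipping.

    Matches heatmap preparation: kernel-5 running mean per row, then the
    whole matrix clipped at its 2nd and 98th centiles (linear-interpolation
    quantiles). Optional per-row z-scoring is exposed on both sides of the
    smoother because the order is a free choice.
    """
    m = np.asarray(matrix, dtype=float).copy()

    def _z(x):
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (x - x.mean(axis=1, keepdims=True)) / sd

    if zscore_rows and zscore_before_smoothing:
        m = _z(m)
    m = np.apply_along_axis(running_mean, 1, m, kernel)
    if zscore_rows and not zscore_before_smoothing:
        m = _z(m)
    lo, hi = np.percentile(m, lo_hi_centiles)
    return np.clip(m, lo, hi)


def kmeans_cluster(
    features: np.ndarray, k: int, n_starts: int = 100, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Best-of-``n_starts`` k-means; labels canonicalized by cluster size.

    Returns (labels, inertia). Labels are renumbered so cluster 0 is the
    largest (figure-independent, reproducible ordering); ties broken by
    centroid norm then original label.
    """
    features = np.asarray(features, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if features.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw = km.fit_predict(features)
    order = _canonical_order(raw, km.cluster_centers_)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw], float(km.inertia_)


def _canonical_order(labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    sizes = np.bincount(labels, minlength=len(centers))
    norms = np.linalg.norm(centers, axis=1)
    return np.lexsort((np.arange(len(centers)), -norms, -sizes))
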