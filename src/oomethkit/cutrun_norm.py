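"""CUT&RUN normalization anchored to stably expressed genes.

CUT&RUN libraries from oocytes carry no spike-in; instead, libraries are
rescaled so that each contributes the same signal mass over the gene
bodies (+5 kb flanks) of genes whose expression is stable across
genotypes, on the assumption that chromatin marks over such regions are on
average unchanged. Tile counts are additionally min-shifted to the 15th
centile to absorb detection-limit and background differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from oomethkit.quantify import CountTable

logger = logging.getLogger(__name__)


@dataclass
class StableGeneSet:
    """Genes stably expressed across genotypes, with the selection audit."""

    gene_ids: pd.Index
    audit: pd.DataFrame  # per selected gene: log2cpm, log2fc
    cpm_thresh: float
    fc_thresh: float


def select_stable_genes(
    log2cpm: pd.Series,
    log2fc: pd.Series,
    cpm_thresh: float = 0.25,
    fc_thresh: float = 0.25,
) -> StableGeneSet:
    """Select genes with |log2CPM| > cpm_thresh and |log2FC| < fc_thresh.

    The expression criterion is applied on the absolute value as stated
    (so strongly negative log2CPM also qualifies); pass
    ``strict_positive=True`` via :func:`select_stable_genes_strict` for the
    expression-above-threshold variant.
    """
    log2cpm, log2fc = log2cpm.align(log2fc, join="inner")
    mask = (log2cpm.abs() > cpm_thresh) & (log2fc.abs() < fc_thresh)
    if not mask.any():
        raise ValueError(
            "no stable genes at the given thresholds; relax cpm_thresh/fc_thresh"
        )
    audit = pd.DataFrame({"log2cpm": log2cpm[mask], "log2fc": log2fc[mask]})
    return StableGeneSet(audit.index, audit, cpm_thresh, fc_thresh)


def select_stable_genes_strict(
    log2cpm: pd.Series, log2fc: pd.Series, cpm_thresh: float = 0.25,
    fc_thresh: float = 0.25,
) -> StableGeneSet:
    """Variant requiring log2CPM > cpm_thresh (expressed above threshold)."""
    log2cpm, log2fc = log2cpm.align(log2fc, join="inner")
    mask = (log2cpm > cpm_thresh) & (log2fc.abs() < fc_thresh)
    if not mask.any():
        raise ValueError("no stable genes at the given thresholds")
    audit = pd.DataFrame({"log2cpm": log2cpm[mask], "log2fc": log2fc[mask]})
    return StableGeneSet(audit.index, audit, cpm_thresh, fc_thresh)


def normalize_libraries(
    table: CountTable, stable_window_ids
) -> tuple[pd.DataFrame, pd.Series]:
    """Rescale libraries to equal stable-window signal mass.

    factor_j = (stable-window reads of library j) / (geometric mean over
    libraries); normalized counts = raw / factor_j. The geometric-mean
    anchor keeps the overall scale of the data and makes the factors
    multiply to 1 so no library is privileged.

    Returns (normalized matrix, per-library factors).
    """
    stable_window_ids = pd.Index(stable_window_ids)
    missing = stable_window_ids.difference(table.region_ids)
    if len(missing):
        raise ValueError(f"count table lacks {len(missing)} stable windows")
    totals = table.counts.loc[stable_window_ids].sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero stable-window reads in libraries {bad}")
    geo_mean = float(np.exp(np.log(totals).mean()))
    factors = totals / geo_mean
    normalized = table.counts.div(factors, axis=1)
    return normalized, factors


def nearest_rank_centile(values: np.ndarray, centile: float) -> float:
    """Nearest-rank order statistic: value at rank ceil(c/100 * n)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise ValueError("empty input")
    rank = max(1, math.ceil(centile / 100.0 * n))
    return float(values[rank - 1])


def min_shift(
    values: np.ndarray, centile: float = 15.0, interpolated: bool = False
) -> np.ndarray:
    """Subtract the per-library 15th-centile and clamp negatives at 0.

    The centile is the nearest-rank order statistic by default (what the
    centile of a count distribution naturally is); a linear-interpolation
    quantile is available behind ``interpolated``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if interpolated:
        q = float(np.percentile(values, centile))
    else:
        q = nearest_rank_centile(values, centile)
    return np.maximum(0.0, values - q)
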