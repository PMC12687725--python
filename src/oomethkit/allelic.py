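"""Allele-specific read assignment and quantification for hybrid samples.

Reads from Bl6 x JF1 hybrid embryos are aligned to both parental genomes;
a read is called maternal (Bl6) or paternal (JF1) by the strict minimum of
its mismatch counts against the two genomes, and undefined on ties
(including reads covering no SNP). Allelic library sizes count maternal +
paternal reads only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATERNAL, PATERNAL, UNDEFINED = "maternal", "paternal", "undefined"


@dataclass
class ReadMismatchTable:
    """Per-read mismatch counts against both parental genomes.

    ``reads`` columns: mismatches_maternal, mismatches_paternal,
    mapped_feature, and (synthetic data only) true_origin.
    """

    reads: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.reads
        if (r["mismatches_maternal"] < 0).any() or (r["mismatches_paternal"] < 0).any():
            raise ValueError("mismatch counts must be >= 0")


@dataclass
class AllelicCounts:
    """Per-feature maternal/paternal/undefined counts and library size."""

    counts: pd.DataFrame  # feature x {maternal, paternal, undefined}
    allelic_library_size: int  # maternal + paternal reads

    def maternal_fraction(self) -> pd.Series:
        tot = self.counts[MATERNAL] + self.counts[PATERNAL]
        return self.counts[MATERNAL] / tot.where(tot > 0)


def assign_reads(table: ReadMismatchTable) -> pd.Series:
    """Label each read by the strict minimum-mismatch rule (tie: undefined)."""
    m = table.reads["mismatches_maternal"].to_numpy()
    p = table.reads["mismatches_paternal"].to_numpy()
    labels = np.where(m < p, MATERNAL, np.where(p < m, PATERNAL, UNDEFINED))
    return pd.Series(labels, index=table.reads.index, name="allele")


def allelic_expression(
    table: ReadMismatchTable,
    exonic_lengths: pd.Series | None = None,
    psc: float = 0.1,
) -> tuple[AllelicCounts, pd.DataFrame | None]:
    """Per-gene allelic counts and (optionally) allelic log2 RPKM.

    The allelic library size (maternal + paternal reads, undefined
    excluded) is shared between the two alleles so per-allele RPKM values
    are directly comparable.
    """
    labels = assign_reads(table)
    df = table.reads.assign(allele=labels)
    counts = (
        df.groupby(["mapped_feature", "allele"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[MATERNAL, PATERNAL, UNDEFINED], fill_value=0)
    )
    libsize = int(counts[MATERNAL].sum() + counts[PATERNAL].sum())
    if libsize == 0:
        raise ValueError("allelic library size is 0 (all reads undefined)")
    result = AllelicCounts(counts, libsize)
    rpkm = None
    if exonic_lengths is not None:
        lengths = exonic_lengths.loc[counts.index].astype(float)
        rpkm = pd.DataFrame(index=counts.index)
        for allele in (MATERNAL, PATERNAL):
            r = counts[allele] / (lengths / 1e3) / (libsize / 1e6)
            rpkm[allele] = np.log2(r + psc) - np.log2(psc)
    return result, rpkm


def allelic_methylation(
    calls: pd.DataFrame, regions, min_reads_per_allele: int = 5
) -> pd.DataFrame:
    """Pooled per-region methylation percent for each parental allele.

    ``calls`` is a MethCallTable-style frame with a ``haplotype`` column in
    {maternal, paternal, untagged}; untagged calls are excluded. Alleles
    with fewer than ``min_reads_per_allele`` informative calls in a region
    are reported NA.
    """
    tagged = calls[calls["haplotype"].isin([MATERNAL, PATERNAL])]
    out = {}
    for r in regions:
        sub = tagged[
            (tagged["chrom"] == r.chrom)
            & (tagged["pos"] >= r.start)
            & (tagged["pos"] < r.end)
            & (tagged["context"] == "CpG")
        ]
        row = {}
        for allele in (MATERNAL, PATERNAL):
            a = sub[sub["haplotype"] == allele]
            tot = a["total"].sum()
            if tot < min_reads_per_allele:
                row[allele] = np.nan
            else:
                row[allele] = 100.0 * a["methylated"].sum() / tot
        out[r.id] = row
    return pd.DataFrame.from_dict(out, orient="index")
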