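"""Genomic interval containers, BED/bedGraph I/O and window construction.

All coordinates are 0-based half-open throughout the package; BED is the
on-disk format and 1-based positions appear only in log messages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed line in an interval file (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic region in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor((start+end)/2): deterministic center of even-width regions
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene(GenomicInterval):
    """A gene interval; TSS/TES derive from strand orientation."""

    exonic_length: int = 0
    promoter_class: str = "non-CGI"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.exonic_length > self.width:
            raise ValueError("exonic_length exceeds gene length")

    @property
    def tss(self) -> int:
        """Transcription start as a point coordinate (+: start, -: end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end as a point coordinate (+: end, -: start)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class CpGIsland(GenomicInterval):
    """A CpG island with its genomic sequence attached."""

    sequence: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.sequence and len(self.sequence) != self.width:
            raise ValueError("CGI sequence length must equal interval width")


@dataclass
class GenomeAnnotation:
    """Genes, CpG islands and intergenic tiles on a shared genome."""

    genes: list[Gene] = field(default_factory=list)
    cgis: list[CpGIsland] = field(default_factory=list)
    tiles: list[GenomicInterval] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def chrom_size(self, chrom: str) -> int:
        return self.chrom_sizes.get(chrom, np.iinfo(np.int64).max)


def read_intervals(path, fmt: str = "BED") -> list[GenomicInterval]:
    """Read BED (3-6 column) or headerless TSV intervals.

    Coordinates on disk are taken as 0-based half-open (BED convention).
    Input order is preserved. Malformed lines raise :class:`ParseError`
    with the offending line number.
    """
    if fmt not in {"BED", "TSV"}:
        raise ValueError(f"unknown format {fmt!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else f"iv{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, strand=strand, id=name)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_signal_track(intervals, values, path) -> None:
    """Write a bedGraph track (chrom, start, end, value; 6 sig. digits).

    NaN values are written as ``nan`` and counted in a log warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(intervals):
        raise ValueError(
            f"{len(intervals)} intervals but {len(values)} values"
        )
    n_nan = int(np.isnan(values).sum())
    if n_nan:
        logger.warning("write_signal_track: %d NaN values written as 'nan'", n_nan)
    with open(path, "w") as fh:
        for iv, v in zip(intervals, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


def _clip(start: int, end: int, chrom_size: int) -> tuple[int, int]:
    return max(0, start), min(end, chrom_size)


def make_windows(
    annotation: GenomeAnnotation,
    mode: str,
    *,
    upstream: int = 1500,
    downstream: int = 500,
    flank: int = 5000,
    width: int = 533,
    tile_width: int = 500,
):
    """Build the window systems used downstream of counting.

    Modes (offsets are applied on the transcription axis, so "upstream"
    means 5' of the TSS on both strands):

    ``promoter``
        [TSS - upstream, TSS + downstream); defaults -1500/+500.
    ``genebody``
        [TSS + downstream, TES); genes whose body would be empty are
        excluded and logged.
    ``flanked_genebody``
        [gene start - flank, gene end + flank); default 5 kb flanks.
    ``cgi_center``
        fixed ``width`` window centred on the CGI midpoint (median CGI
        width, 533 nt, by default); even-width midpoint is
        floor((start+end)/2).
    ``tiles``
        the annotation's tiles re-cut into non-overlapping ``tile_width``
        bins.

    Windows are clipped at chromosome bounds; clipped cgi_center windows
    are logged.
    """
    out: list[GenomicInterval] = []
    if mode == "promoter" or mode == "genebody":
        for g in annotation.genes:
            size = annotation.chrom_size(g.chrom)
            if mode == "promoter":
                if g.strand == "+":
                    s, e = g.tss - upstream, g.tss + downstream
                else:
                    s, e = g.tss - downstream, g.tss + upstream
            else:
                if g.strand == "+":
                    s, e = g.tss + downstream, g.tes
                else:
                    s, e = g.tes, g.tss - downstream
            s, e = _clip(s, e, size)
            if e <= s:
                logger.warning("make_windows: empty %s for gene %s, excluded", mode, g.id)
                continue
            out.append(GenomicInterval(g.chrom, s, e, strand=g.strand, id=g.id))
    elif mode == "flanked_genebody":
        for g in annotation.genes:
            s, e = _clip(g.start - flank, g.end + flank, annotation.chrom_size(g.chrom))
            out.append(GenomicInterval(g.chrom, s, e, strand=g.strand, id=g.id))
    elif mode == "cgi_center":
        if width <= 0:
            raise ValueError("cgi_center width must be positive")
        half = width // 2
        for c in annotation.cgis:
            mid = c.midpoint
            s, e = mid - half, mid - half + width
            cs, ce = _clip(s, e, annotation.chrom_size(c.chrom))
            if (cs, ce) != (s, e):
                logger.warning("make_windows: cgi_center window for %s clipped", c.id)
            out.append(GenomicInterval(c.chrom, cs, ce, id=c.id))
    elif mode == "tiles":
        for t in annotation.tiles:
            n = math.floor(t.width / tile_width)
            for i in range(n):
                s = t.start + i * tile_width
                out.append(
                    GenomicInterval(t.chrom, s, s + tile_width, id=f"{t.id}_bin{i}")
                )
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return out


def flip_strand(gene: Gene) -> Gene:
    """Strand-flipped copy of a gene about the same span (test helper)."""
    return replace(gene, strand="-" if gene.strand == "+" else "+")
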