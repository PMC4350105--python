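"""Genomic coordinate primitives: intervals, genes, promoters, CpG islands.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
GTF-style 1-based inclusive starts are converted on input (see :mod:`ncmeth.io`)
and never appear internally.

The promoter of a gene is the ±``flank`` window around its transcription start
site (TSS), taken at the stranded 5' end of the locus: the genomic start for
``+``-strand genes and the genomic end for ``-``-strand genes.  pri-miRNA loci
follow the same rule.  CpG-island (CGI) shores are the ``shore_width`` windows
immediately flanking a CGI on either side, abutting it with no gap.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
GENE_CLASSES = ("coding", "lncRNA", "miRNA")
BIOTYPES = ("intergenic", "intragenic", "overlapping", "unassigned")


class IntervalError(ValueError):
    """A genomic interval violates its invariants (e.g. end <= start)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome.

    ``end == start`` (an empty interval) is representable — degenerate shores
    at chromosome edges need it — but empty intervals are rejected by the
    overlap operations.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"negative start {self.start} on {self.chrom}")
        if self.end < self.start:
            raise IntervalError(
                f"end {self.end} < start {self.start} on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise IntervalError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """A gene locus with its class (coding / lncRNA / pri-miRNA) and, once
    classified, its position relative to protein-coding gene bodies."""

    gene_id: str
    interval: GenomicInterval
    gene_class: str
    biotype: str = "unassigned"
    host_gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.biotype == "intragenic" and self.host_gene_id is None:
            raise ValueError("intragenic gene without host_gene_id")

    @property
    def tss(self) -> int:
        """Stranded 5' end; unstranded loci are treated as '+' (logged)."""
        if self.interval.strand == "-":
            return self.interval.end
        if self.interval.strand == ".":
            logger.info("gene %s is unstranded; TSS taken at genomic start", self.gene_id)
        return self.interval.start


@dataclass(frozen=True)
class PromoterRegion:
    """TSS ± flank window.  ``truncated`` marks clamping at coordinate 0."""

    gene_id: str
    interval: GenomicInterval
    tss: int
    flank: int
    truncated: bool = False


@dataclass(frozen=True)
class CGIRegion:
    """A CpG island with its two flanking shores in genome orientation:
    ``five_prime_shore`` is the genome-left (lower-coordinate) shore.  Gene
    strand reorients laterality via :meth:`shores_for_strand`."""

    interval: GenomicInterval
    five_prime_shore: GenomicInterval
    three_prime_shore: GenomicInterval

    def shores_for_strand(self, strand: str) -> tuple[GenomicInterval, GenomicInterval]:
        """(5' shore, 3' shore) relative to a gene on ``strand``."""
        if strand == "-":
            return self.three_prime_shore, self.five_prime_shore
        return self.five_prime_shore, self.three_prime_shore


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 across chromosomes."""
    for iv in (a, b):
        if iv.end <= iv.start:
            raise IntervalError(f"empty or malformed interval {iv}")
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, denominator: str = "a"
) -> float:
    """Overlap as a fraction of a chosen interval's length.

    ``denominator`` is one of ``a``, ``b``, ``shorter`` or ``either_max``;
    ``either_max`` returns max(fraction-of-a, fraction-of-b), i.e. the
    "greater than 50% of either region" reading used for CGI-confined calls.
    """
    ov = overlap_length(a, b)
    if denominator == "a":
        denom = a.length
    elif denominator == "b":
        denom = b.length
    elif denominator == "shorter":
        denom = min(a.length, b.length)
    elif denominator == "either_max":
        return max(ov / a.length, ov / b.length)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise IntervalError("zero-length denominator interval")
    return ov / denom


def build_promoter(gene: GeneModel, flank: int = 2000) -> PromoterRegion:
    """±flank window around the stranded TSS, clamped at coordinate 0."""
    tss = gene.tss
    start = tss - flank
    truncated = start < 0
    if truncated:
        logger.info("promoter of %s truncated at chromosome start", gene.gene_id)
        start = 0
    interval = GenomicInterval(
        gene.interval.chrom, start, tss + flank, gene.interval.strand
    )
    return PromoterRegion(gene.gene_id, interval, tss, flank, truncated)


def build_shores(cgi_interval: GenomicInterval, shore_width: int = 2000) -> CGIRegion:
    """Attach the two shore_width flanks to a CGI, clamping at 0.

    shore_width == 0 yields empty (degenerate) shores.
    """
    if shore_width == 0:
        logger.info("shore width 0: degenerate shores for CGI %s", cgi_interval)
    c = cgi_interval.chrom
    left = GenomicInterval(c, max(0, cgi_interval.start - shore_width), cgi_interval.start)
    if cgi_interval.start - shore_width < 0:
        logger.info("left shore of CGI %s truncated at chromosome start", cgi_interval)
    right = GenomicInterval(c, cgi_interval.end, cgi_interval.end + shore_width)
    return CGIRegion(cgi_interval, left, right)


class IntervalIndex:
    """Per-chromosome interval tree over arbitrary payloads."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object) -> None:
        if iv.end > iv.start:  # interval trees cannot hold empty intervals
            self._trees[iv.chrom].addi(iv.start, iv.end, payload)

    def overlapping(self, iv: GenomicInterval) -> list:
        """Payloads of indexed intervals sharing >=1 bp with ``iv``."""
        if iv.chrom not in self._trees or iv.end <= iv.start:
            return []
        return [hit.data for hit in self._trees[iv.chrom].overlap(iv.start, iv.end)]


def classify_biotype(
    ncrna: GeneModel,
    coding_index: IntervalIndex,
) -> tuple[str, Optional[str]]:
    """Position of an ncRNA relative to protein-coding gene bodies.

    intergenic: no coding-gene body overlap; intragenic: fully contained in a
    coding body (host = largest container, ties by lexicographic id);
    overlapping: partial (>=1 bp) body overlap otherwise.  Strand is ignored.
    """
    hits: list[GeneModel] = coding_index.overlapping(ncrna.interval)
    if not hits:
        return "intergenic", None
    containing = [g for g in hits if g.interval.contains(ncrna.interval)]
    if containing:
        host = min(containing, key=lambda g: (-g.interval.length, g.gene_id))
        return "intragenic", host.gene_id
    return "overlapping", None


def classify_biotypes(
    ncrnas: Sequence[GeneModel], coding_genes: Sequence[GeneModel]
) -> list[GeneModel]:
    """Classify a batch of ncRNAs; returns new GeneModels with biotype set."""
    if not coding_genes:
        logger.warning("empty coding-gene set: all ncRNAs classified intergenic")
    index = IntervalIndex((g.interval, g) for g in coding_genes)
    out = []
    for nc in ncrnas:
        biotype, host = classify_biotype(nc, index)
        out.append(replace(nc, biotype=biotype, host_gene_id=host))
    return out
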