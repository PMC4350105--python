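"""Promoter-level differential methylation and its CGI context.

A gene is called differentially methylated when at least one DMR of a
direction overlaps its promoter by at least 50% of the DMR's length.  Each
called promoter is then assigned one of five mutually exclusive patterns
describing where the aberrant methylation sits relative to the promoter's
CpG islands:

1. ``cgi_confined`` — the DMR-CGI overlap exceeds 50% of either region;
2. ``five_prime_shore`` — methylation strictly 5' of every promoter CGI,
   on the 5' shore (laterality follows gene strand);
3. ``three_prime_shore`` — likewise strictly 3';
4. ``partial_overlap`` — shore-overlapping or sub-50% CGI overlap;
5. ``no_cgi`` — the promoter contains no CGI.

The decision order 5 -> 1 -> 2 -> 3 -> 4 makes the classes exhaustive and
exclusive; when several supporting DMRs disagree, the DMR with the largest
promoter overlap decides (ties: lowest pattern number, flagged).  The same
50%-of-DMR rule is applied to CGI bodies and shores directly, and
TSS-centered 10-bp aberrant-methylation frequency profiles support the
positional summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .dmr import DMR
from .genome import (
    CGIRegion,
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    PromoterRegion,
    overlap_fraction,
    overlap_length,
)

logger = logging.getLogger(__name__)

PATTERN_LABELS = {
    1: "cgi_confined",
    2: "five_prime_shore",
    3: "three_prime_shore",
    4: "partial_overlap",
    5: "no_cgi",
}


@dataclass(frozen=True)
class PromoterCall:
    """A gene called differentially methylated in one direction."""

    gene_id: str
    direction: str  # hyper | hypo
    dmr_indices: tuple[int, ...]  # indices into the DMR list
    ambiguous: bool = False  # gene carries calls in both directions


@dataclass(frozen=True)
class PatternCall:
    """Promoter call with its CGI-context pattern."""

    gene_id: str
    direction: str
    pattern: int
    dmr_indices: tuple[int, ...]
    cgi_ids: tuple[int, ...]  # indices of promoter-resident CGIs
    tie_flagged: bool = False

    @property
    def pattern_name(self) -> str:
        return PATTERN_LABELS[self.pattern]


def map_dmrs_to_promoters(
    dmrs: Sequence[DMR],
    promoters: dict[str, PromoterRegion],
    min_dmr_fraction: float = 0.5,
) -> list[PromoterCall]:
    """Promoter-level differential calls from the >=50%-of-DMR overlap rule.

    A gene may be called in both directions by distinct DMRs; both calls are
    returned, flagged ambiguous.
    """
    index = IntervalIndex((d.interval, i) for i, d in enumerate(dmrs))
    calls: list[PromoterCall] = []
    for gene_id, prom in promoters.items():
        support: dict[str, list[int]] = {"hyper": [], "hypo": []}
        for i in index.overlapping(prom.interval):
            d = dmrs[i]
            frac = overlap_fraction(d.interval, prom.interval, denominator="a")
            if frac >= min_dmr_fraction:
                support[d.direction].append(i)
        directions = [dr for dr in ("hyper", "hypo") if support[dr]]
        ambiguous = len(directions) == 2
        if ambiguous:
            logger.info("gene %s called in both directions", gene_id)
        for dr in directions:
            calls.append(
                PromoterCall(gene_id, dr, tuple(sorted(support[dr])), ambiguous)
            )
    return calls


def map_dmrs_to_cgis(
    dmrs: Sequence[DMR],
    cgi_regions: Sequence[CGIRegion],
    min_dmr_fraction: float = 0.5,
) -> pd.DataFrame:
    """Differential CGI bodies and shores under the same >=50%-of-DMR rule.

    Returns one row per CGI with the set of directions called on the body,
    the 5' (genome-left) shore and the 3' (genome-right) shore.
    """
    index = IntervalIndex((d.interval, i) for i, d in enumerate(dmrs))

    def called(region: GenomicInterval) -> set[str]:
        out = set()
        if region.end <= region.start:
            return out
        for i in index.overlapping(region):
            d = dmrs[i]
            if overlap_fraction(d.interval, region, denominator="a") >= min_dmr_fraction:
                out.add(d.direction)
        return out

    rows = []
    for ci, cgi in enumerate(cgi_regions):
        rows.append(
            {
                "cgi_index": ci,
                "chrom": cgi.interval.chrom,
                "start": cgi.interval.start,
                "end": cgi.interval.end,
                "body": ",".join(sorted(called(cgi.interval))),
                "five_prime_shore": ",".join(sorted(called(cgi.five_prime_shore))),
                "three_prime_shore": ",".join(sorted(called(cgi.three_prime_shore))),
            }
        )
    return pd.DataFrame(rows)


def _dmr_pattern_vs_cgis(
    dmr: DMR,
    strand: str,
    promoter_cgis: list[tuple[int, CGIRegion]],
    cgi_confined_fraction: float = 0.5,
) -> int:
    """Pattern of a single DMR against the promoter's CGIs (patterns 1-4)."""
    iv = dmr.interval
    for _, cgi in promoter_cgis:
        if overlap_length_safe(iv, cgi.interval) > 0:
            if overlap_fraction(iv, cgi.interval, "either_max") > cgi_confined_fraction:
                return 1
    # strictly 5'/3': zero overlap with every CGI, on the matching side,
    # and touching the corresponding shore of the nearest CGI
    five_of_all = all(_is_strictly_5prime(iv, cgi.interval, strand) for _, cgi in promoter_cgis)
    three_of_all = all(_is_strictly_3prime(iv, cgi.interval, strand) for _, cgi in promoter_cgis)
    if five_of_all or three_of_all:
        # shores follow gene strand; unstranded genes default to genome left=5'
        for _, cgi in promoter_cgis:
            five_shore, three_shore = cgi.shores_for_strand(strand)
            if five_of_all and overlap_length_safe(iv, five_shore) > 0:
                return 2
            if three_of_all and overlap_length_safe(iv, three_shore) > 0:
                return 3
    return 4


def overlap_length_safe(a: GenomicInterval, b: GenomicInterval) -> int:
    """overlap_length tolerating empty intervals (returns 0)."""
    if a.end <= a.start or b.end <= b.start:
        return 0
    return overlap_length(a, b)


def _is_strictly_5prime(dmr: GenomicInterval, cgi: GenomicInterval, strand: str) -> bool:
    if strand == "-":
        return dmr.start >= cgi.end
    return dmr.end <= cgi.start


def _is_strictly_3prime(dmr: GenomicInterval, cgi: GenomicInterval, strand: str) -> bool:
    if strand == "-":
        return dmr.end <= cgi.start
    return dmr.start >= cgi.end


def classify_pattern(
    call: PromoterCall,
    promoter: PromoterRegion,
    cgis: Sequence[CGIRegion],
    dmrs: Sequence[DMR],
) -> PatternCall:
    """Assign the five-class CGI-context pattern to one promoter call."""
    if not call.dmr_indices:
        raise ValueError(f"called gene {call.gene_id} has no supporting DMR")
    promoter_cgis = [
        (ci, cgi)
        for ci, cgi in enumerate(cgis)
        if overlap_length_safe(cgi.interval, promoter.interval) > 0
    ]
    cgi_ids = tuple(ci for ci, _ in promoter_cgis)
    if not promoter_cgis:
        return PatternCall(call.gene_id, call.direction, 5, call.dmr_indices, ())

    strand = promoter.interval.strand
    if strand == ".":
        logger.info(
            "gene %s unstranded: shore laterality defaults to genome left=5'",
            call.gene_id,
        )
    # the DMR with the largest promoter overlap decides; ties -> lowest pattern
    scored: list[tuple[int, int]] = []  # (promoter overlap bp, pattern)
    for di in call.dmr_indices:
        d = dmrs[di]
        ov = overlap_length_safe(d.interval, promoter.interval)
        scored.append((ov, _dmr_pattern_vs_cgis(d, strand, promoter_cgis)))
    best_ov = max(ov for ov, _ in scored)
    best_patterns = sorted({p for ov, p in scored if ov == best_ov})
    tie = len(best_patterns) > 1
    if tie:
        logger.info(
            "gene %s: tied DMR overlaps with patterns %s; lowest wins",
            call.gene_id,
            best_patterns,
        )
    return PatternCall(
        call.gene_id, call.direction, best_patterns[0], call.dmr_indices, cgi_ids, tie
    )


def classify_patterns(
    calls: Sequence[PromoterCall],
    promoters: dict[str, PromoterRegion],
    cgis: Sequence[CGIRegion],
    dmrs: Sequence[DMR],
) -> list[PatternCall]:
    return [classify_pattern(c, promoters[c.gene_id], cgis, dmrs) for c in calls]


@dataclass
class ProfileMatrix:
    """Binary promoter x 10-bp-window occupancy of direction-specific DMRs,
    in stranded TSS-relative orientation (column 0 = most upstream)."""

    gene_ids: list[str]
    matrix: np.ndarray  # shape (n_promoters, 2*flank/window), values 0/1
    window: int
    flank: int

    @property
    def frequency(self) -> np.ndarray:
        """Per-window mean across promoters (the average frequency curve)."""
        if self.matrix.shape[0] == 0:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.mean(axis=0)

    @property
    def positions(self) -> np.ndarray:
        """Stranded window-center offsets from the TSS, in bp."""
        return -self.flank + self.window * (np.arange(self.matrix.shape[1]) + 0.5)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"w{int(p)}" for p in self.positions]
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=cols)


def tss_profile(
    promoters: dict[str, PromoterRegion],
    dmrs: Sequence[DMR],
    direction: str,
    window: int = 10,
) -> ProfileMatrix:
    """Mark each stranded 10-bp promoter window overlapping a DMR of the
    given direction."""
    flanks = {p.flank for p in promoters.values()}
    if len(flanks) > 1:
        raise ValueError("promoters must share one flank size")
    flank = flanks.pop() if flanks else 0
    n_win = (2 * flank) // window
    index = IntervalIndex(
        (d.interval, d) for d in dmrs if d.direction == direction
    )
    gene_ids = sorted(promoters)
    mat = np.zeros((len(gene_ids), n_win), dtype=np.uint8)
    for r, gid in enumerate(gene_ids):
        prom = promoters[gid]
        hits = index.overlapping(prom.interval)
        if not hits:
            continue
        chrom = prom.interval.chrom
        strand = prom.interval.strand
        for w in range(n_win):
            rel_lo = -flank + w * window
            rel_hi = rel_lo + window
            if strand == "-":
                g_lo, g_hi = prom.tss - rel_hi, prom.tss - rel_lo
            else:
                g_lo, g_hi = prom.tss + rel_lo, prom.tss + rel_hi
            if g_lo < 0:
                g_lo = 0
            if g_hi <= g_lo:
                continue
            win_iv = GenomicInterval(chrom, g_lo, g_hi)
            if any(overlap_length_safe(win_iv, d.interval) > 0 for d in hits):
                mat[r, w] = 1
    return ProfileMatrix(gene_ids, mat, window, flank)


def host_concordance(
    calls: Sequence[PromoterCall],
    ncrnas: Sequence[GeneModel],
    promoters: dict[str, PromoterRegion],
) -> pd.DataFrame:
    """Methylation concordance of intragenic ncRNAs with their host genes.

    The ncRNA/host promoter overlap is classed as >=50% or <50% by the
    larger of the two single-denominator fractions; a pair is concordant
    when both promoters are called and the directions match.
    """
    by_gene: dict[str, set[str]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, set()).add(c.direction)
    rows = []
    for nc in ncrnas:
        if nc.biotype != "intragenic" or nc.host_gene_id is None:
            continue
        if nc.gene_id not in promoters or nc.host_gene_id not in promoters:
            continue
        p_nc = promoters[nc.gene_id].interval
        p_host = promoters[nc.host_gene_id].interval
        frac = (
            overlap_fraction(p_nc, p_host, "either_max")
            if overlap_length_safe(p_nc, p_host) > 0
            else 0.0
        )
        nc_dirs = by_gene.get(nc.gene_id, set())
        host_dirs = by_gene.get(nc.host_gene_id, set())
        rows.append(
            {
                "ncrna": nc.gene_id,
                "host": nc.host_gene_id,
                "overlap_fraction": frac,
                "overlap_class": "ge50" if frac >= 0.5 else "lt50",
                "ncrna_called": bool(nc_dirs),
                "host_called": bool(host_dirs),
                "concordant": bool(nc_dirs & host_dirs),
            }
        )
    return pd.DataFrame(rows)


def concordance_rate_lt50(pairs: pd.DataFrame) -> float:
    """Direction-concordance rate among the <50% promoter-overlap pairs."""
    sub = pairs[pairs["overlap_class"] == "lt50"]
    if len(sub) == 0:
        return float("nan")
    return float(sub["concordant"].mean())


def region_set_enrichment(
    called_genes: set[str],
    universe: Sequence[str],
    region_set: Sequence[GenomicInterval],
    promoters: dict[str, PromoterRegion],
) -> tuple[float, float]:
    """Fisher enrichment of called genes among those whose promoter touches
    a region set (>=1 bp).  Returns (odds ratio with Haldane 0.5 correction
    when any cell is zero, two-sided Fisher exact p)."""
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    if not called_genes <= set(universe):
        raise ValueError("called set must be contained in the universe")
    if set(universe) == called_genes:
        logger.warning("called set equals the universe: enrichment degenerate")
    index = IntervalIndex((iv, i) for i, iv in enumerate(region_set))
    in_region = {
        g for g in universe if g in promoters and index.overlapping(promoters[g].interval)
    }
    a = len(called_genes & in_region)
    b = len(called_genes - in_region)
    c = len(in_region - called_genes)
    d = len(universe) - a - b - c
    _, p = sp_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
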