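"""Synthetic cohort generator with ground truth.

Emulates the study design the pipeline targets: a tumor and a normal cohort
of capture-seq methylomes summarized as read counts on a fixed 100-bp bin
grid, a gene annotation with coding genes, lncRNAs and pri-miRNA loci laid
out to realize a requested biotype mix, CGI-structured promoters, and
differential methylation "spikes" of each of the five CGI-context pattern
classes written into the tumor group at a known fold change.  Coupled
expression tables (FPKM-like cell lines for lncRNAs, an RPM cohort matrix
for miRNAs) and promoter histone-density tracks are generated from the same
truth, and everything is recorded in a machine-readable truth manifest so
that recovery can be scored exactly.

The count model is negative binomial (mean ``m``, dispersion ``k``, variance
``m + m^2/k``) with per-sample library-size factors drawn log-uniformly:
capture-seq cohort counts are overdispersed relative to Poisson and library
depth varies between samples.  CGI bins get an elevated baseline (capture
enriches CpG-dense DNA).  Spike regions are placed so that every
pattern-defining overlap fraction clears its 50% threshold with at least a
10% margin — recovery tests should fail on statistics, not on knife-edge
geometry.

What this generator does not emulate: read-level artifacts (mappability,
GC bias, fragment-size effects), copy-number confounding, spatial
autocorrelation of methylation beyond the spiked regions, and biological
heterogeneity within the tumor group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import (
    CGIRegion,
    GeneModel,
    GenomicInterval,
    PromoterRegion,
    build_promoter,
    build_shores,
    classify_biotypes,
    overlap_length,
)
from .io import BinTrack

PATTERNS = (1, 2, 3, 4, 5)
PATTERN_NAMES = {
    1: "cgi_confined",
    2: "five_prime_shore",
    3: "three_prime_shore",
    4: "partial_overlap",
    5: "no_cgi",
}

# Spike regions in stranded TSS-relative coordinates [a, b), chosen for a
# CGI at TSS +/- 400 so every pattern's defining fractions clear 50% by a
# wide margin (see classify_pattern):
#   1: the CGI itself (either-region overlap 1.0)
#   2/3: mid-shore block, zero CGI overlap
#   4: straddles the CGI 3' edge (CGI overlap 300/800 = 0.375, of DMR 0.167)
#   5: TSS-centered block in a CGI-less promoter
_SPIKE_OFFSETS = {
    1: (-400, 400),
    2: (-1600, -800),
    3: (800, 1600),
    4: (100, 1900),
    5: (-400, 400),
}
_CGI_HALF_WIDTH = 400


class CapacityError(ValueError):
    """The requested genes do not fit in the configured genome."""


class ConfigConflictError(ValueError):
    """The spike table is inconsistent with the generated CGI layout."""


@dataclass
class SpikeSpec:
    """One designed differential-methylation event.

    ``gene_id`` may be None, in which case a suitable target ncRNA (with or
    without a promoter CGI, as the pattern requires) is assigned during
    annotation simulation.  ``coupling`` links the spike to expression:
    ``silencing`` (hyper + expression down), ``activating`` (hypo +
    expression up) or ``none``.
    """

    direction: str  # hyper | hypo
    pattern: int
    fold_change: float = 4.0
    coupling: str = "none"
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"bad pattern {self.pattern!r}")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.coupling not in ("silencing", "activating", "none"):
            raise ValueError(f"bad coupling {self.coupling!r}")


def default_spike_table() -> list[SpikeSpec]:
    """One hyper and one hypo spike per pattern; a mix of expression
    couplings including uncoupled controls."""
    hyper_coupling = {1: "silencing", 2: "silencing", 3: "none", 4: "silencing", 5: "none"}
    hypo_coupling = {1: "activating", 2: "none", 3: "activating", 4: "none", 5: "activating"}
    spikes = [SpikeSpec("hyper", p, coupling=hyper_coupling[p]) for p in PATTERNS]
    spikes += [SpikeSpec("hypo", p, coupling=hypo_coupling[p]) for p in PATTERNS]
    return spikes


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults give a minutes-scale toy genome: 2 chromosomes x 2 Mb on a
    100-bp grid, 200 genes, 10 normal vs 20 tumor samples, baseline 100
    reads/bin with NB dispersion 10, fold-4 spikes.
    """

    n_chrom: int = 2
    chrom_length: int = 2_000_000
    bin_width: int = 100
    n_coding: int = 100
    n_lncrna: int = 80
    n_mirna: int = 20
    frac_intragenic: float = 0.3
    frac_overlapping: float = 0.2
    cgi_promoter_fraction: float = 0.6
    n_tumor: int = 20
    n_normal: int = 10
    baseline_mean: float = 100.0
    dispersion: float = 10.0
    cgi_enrichment: float = 3.0
    library_factor_range: tuple[float, float] = (0.8, 1.25)
    promoter_flank: int = 2000
    shore_width: int = 2000
    fold_expression: float = 4.0
    expression_log2_sd: float = 0.25
    histone_fold: float = 3.0
    spikes: Optional[list[SpikeSpec]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length % self.bin_width:
            raise ValueError("bin_width must divide chrom_length")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need >= 2 samples per group")
        if self.frac_intragenic + self.frac_overlapping > 1:
            raise ValueError("biotype fractions exceed 1")
        if isinstance(self.library_factor_range, list):
            self.library_factor_range = tuple(self.library_factor_range)
        if self.spikes is not None:
            self.spikes = [
                SpikeSpec(**s) if isinstance(s, dict) else s for s in self.spikes
            ]


@dataclass(frozen=True)
class SpikeRecord:
    """A realized spike: its genomic region and truth labels."""

    gene_id: str
    interval: GenomicInterval
    direction: str
    pattern: int
    fold_change: float
    coupling: str


@dataclass
class TruthManifest:
    """Ground truth of one simulated cohort."""

    spikes: list[SpikeRecord]
    biotypes: dict[str, tuple[str, Optional[str]]]  # gene_id -> (biotype, host)

    @property
    def silencing_genes(self) -> list[str]:
        return [s.gene_id for s in self.spikes if s.coupling == "silencing"]

    @property
    def activating_genes(self) -> list[str]:
        return [s.gene_id for s in self.spikes if s.coupling == "activating"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": s.gene_id,
                    "chrom": s.interval.chrom,
                    "start": s.interval.start,
                    "end": s.interval.end,
                    "direction": s.direction,
                    "pattern": s.pattern,
                    "fold_change": s.fold_change,
                    "coupling": s.coupling,
                }
                for s in self.spikes
            ]
        )


@dataclass
class Annotation:
    """Genes, promoters and CGIs of a simulated genome."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    promoters: dict[str, PromoterRegion]
    cgis: list[CGIRegion]
    spikes: list[SpikeSpec] = field(default_factory=list)  # resolved targets

    @property
    def coding(self) -> list[GeneModel]:
        return [g for g in self.genes if g.gene_class == "coding"]

    @property
    def ncrnas(self) -> list[GeneModel]:
        return [g for g in self.genes if g.gene_class != "coding"]

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _stranded_interval(chrom: str, tss: int, strand: str, rel: tuple[int, int]) -> GenomicInterval:
    """Map a stranded TSS-relative [a, b) window to genome coordinates."""
    a, b = rel
    if strand == "-":
        return GenomicInterval(chrom, tss - b, tss - a)
    return GenomicInterval(chrom, tss + a, tss + b)


_SLOT = 20_000  # bp reserved per gene: body + promoter + shores + spacing
_SLOT_MARGIN = 5_000


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out a toy genome: coding genes first, then ncRNAs realizing the
    requested biotype mix, then promoter CGIs, then spike target assignment.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    bw = config.bin_width
    n_nc = config.n_lncrna + config.n_mirna
    slots_per_chrom = config.chrom_length // _SLOT
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    total_slots = slots_per_chrom * config.n_chrom

    n_intra = int(round(config.frac_intragenic * n_nc))
    n_over = int(round(config.frac_overlapping * n_nc))
    if config.n_coding == 0:
        n_intra = n_over = 0
    if n_intra + n_over > config.n_coding:
        raise CapacityError("not enough coding genes to host intragenic/overlapping ncRNAs")
    n_inter = n_nc - n_intra - n_over
    slots_needed = config.n_coding + n_inter
    if slots_needed > total_slots:
        raise CapacityError(
            f"genome holds {total_slots} gene slots, {slots_needed} needed"
        )

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    def snap(x: int) -> int:
        return (x // bw) * bw

    # place coding genes in the first slots, intergenic ncRNAs after them
    slot_coords = [
        (chroms[s // slots_per_chrom], (s % slots_per_chrom) * _SLOT)
        for s in range(total_slots)
    ]
    order = rng.permutation(total_slots)

    genes: list[GeneModel] = []
    coding: list[GeneModel] = []
    for i in range(config.n_coding):
        chrom, off = slot_coords[order[i]]
        length = snap(int(rng.integers(6_000, 10_001)))
        start = off + _SLOT_MARGIN
        g = GeneModel(
            f"cg_{i + 1:04d}",
            GenomicInterval(chrom, start, start + length, rand_strand()),
            "coding",
        )
        coding.append(g)
        genes.append(g)

    # ncRNA class labels, shuffled so biotypes hit both classes
    nc_classes = ["lncRNA"] * config.n_lncrna + ["miRNA"] * config.n_mirna
    rng.shuffle(nc_classes)
    host_order = rng.permutation(config.n_coding) if config.n_coding else []
    nc_id = 0

    def next_id(cls: str) -> str:
        nonlocal nc_id
        nc_id += 1
        prefix = "lnc" if cls == "lncRNA" else "mir"
        return f"{prefix}_{nc_id:04d}"

    def nc_length(cls: str) -> int:
        lo, hi = (800, 2_001) if cls == "lncRNA" else (400, 801)
        return snap(int(rng.integers(lo, hi)))

    k = 0
    for _ in range(n_intra):
        host = coding[host_order[k]]
        k += 1
        cls = nc_classes.pop()
        length = nc_length(cls)
        start = host.interval.start + 2_000
        genes.append(
            GeneModel(
                next_id(cls),
                GenomicInterval(host.interval.chrom, start, start + length, rand_strand()),
                cls,
            )
        )
    for _ in range(n_over):
        host = coding[host_order[k]]
        k += 1
        cls = nc_classes.pop()
        length = nc_length(cls)
        start = host.interval.end - 200  # straddles the host 3' boundary
        genes.append(
            GeneModel(
                next_id(cls),
                GenomicInterval(host.interval.chrom, start, start + length, rand_strand()),
                cls,
            )
        )
    for j in range(n_inter):
        chrom, off = slot_coords[order[config.n_coding + j]]
        cls = nc_classes.pop()
        length = nc_length(cls)
        start = off + _SLOT_MARGIN + 1_000
        genes.append(
            GeneModel(
                next_id(cls), GenomicInterval(chrom, start, start + length, rand_strand()), cls
            )
        )

    promoters = {g.gene_id: build_promoter(g, config.promoter_flank) for g in genes}

    # promoter CGIs: a CGI centered on the TSS for a configurable fraction
    cgis: list[CGIRegion] = []
    has_cgi: dict[str, bool] = {}
    for g in genes:
        if rng.random() < config.cgi_promoter_fraction:
            tss = g.tss
            cgi = GenomicInterval(
                g.interval.chrom, tss - _CGI_HALF_WIDTH, tss + _CGI_HALF_WIDTH
            )
            cgis.append(build_shores(cgi, config.shore_width))
            has_cgi[g.gene_id] = True
        else:
            has_cgi[g.gene_id] = False

    spikes = _resolve_spike_targets(config, genes, promoters, cgis, has_cgi, rng)
    return Annotation({c: config.chrom_length for c in chroms}, genes, promoters, cgis, spikes)


def _clean_cgi_layout(gene: GeneModel, promoter: PromoterRegion, cgis, has_cgi) -> bool:
    """True when the promoter's CGI content is exactly what its own layout
    dictates: its own TSS-centered CGI and nothing else (or none at all).
    Spike targets are restricted to such promoters so pattern truth labels
    are unambiguous."""
    overlapping = [
        c
        for c in cgis
        if c.interval.chrom == promoter.interval.chrom
        and overlap_length(c.interval, promoter.interval) > 0
    ]
    if not has_cgi[gene.gene_id]:
        return len(overlapping) == 0
    return len(overlapping) == 1 and overlapping[0].interval.start == gene.tss - _CGI_HALF_WIDTH


def _resolve_spike_targets(config, genes, promoters, cgis, has_cgi, rng) -> list[SpikeSpec]:
    spikes = config.spikes if config.spikes is not None else default_spike_table()
    resolved: list[SpikeSpec] = []
    by_id = {g.gene_id: g for g in genes}
    eligible_cgi = [
        g.gene_id
        for g in genes
        if g.gene_class != "coding"
        and has_cgi[g.gene_id]
        and _clean_cgi_layout(g, promoters[g.gene_id], cgis, has_cgi)
    ]
    eligible_nocgi = [
        g.gene_id
        for g in genes
        if g.gene_class != "coding"
        and not has_cgi[g.gene_id]
        and _clean_cgi_layout(g, promoters[g.gene_id], cgis, has_cgi)
    ]
    rng.shuffle(eligible_cgi)
    rng.shuffle(eligible_nocgi)
    taken: set[str] = set()
    for spec in spikes:
        needs_cgi = spec.pattern != 5
        if spec.gene_id is not None:
            gid = spec.gene_id
            if gid not in by_id:
                raise ConfigConflictError(f"spike targets unknown gene {gid!r}")
            if has_cgi[gid] != needs_cgi:
                raise ConfigConflictError(
                    f"spike pattern {spec.pattern} incompatible with CGI layout of {gid}"
                )
        else:
            pool = eligible_cgi if needs_cgi else eligible_nocgi
            avail = [g for g in pool if g not in taken]
            if not avail:
                raise ConfigConflictError(
                    f"no eligible {'CGI' if needs_cgi else 'CGI-less'} promoter left "
                    f"for a pattern-{spec.pattern} spike "
                    f"(cgi_promoter_fraction={config.cgi_promoter_fraction})"
                )
            gid = avail[0]
        taken.add(gid)
        resolved.append(dataclasses.replace(spec, gene_id=gid))
    return resolved


def spike_region(spec: SpikeSpec, gene: GeneModel) -> GenomicInterval:
    """Genomic interval a spike occupies, from its pattern's stranded
    TSS-relative offsets."""
    return _stranded_interval(
        gene.interval.chrom, gene.tss, gene.interval.strand, _SPIKE_OFFSETS[spec.pattern]
    )


def _mean_arrays(annotation: Annotation, config: SimulationConfig):
    """Per-chromosome baseline means and the tumor-group multiplier."""
    bw = config.bin_width
    base = {
        c: np.full(length // bw, config.baseline_mean)
        for c, length in annotation.chrom_lengths.items()
    }
    cgi_mask = {c: np.zeros(len(v), dtype=bool) for c, v in base.items()}
    for cgi in annotation.cgis:
        iv = cgi.interval
        cgi_mask[iv.chrom][iv.start // bw : -(-iv.end // bw)] = True
    for c in base:  # enrichment applies once even where CGIs overlap
        base[c][cgi_mask[c]] *= config.cgi_enrichment
    tumor_mult = {c: np.ones_like(v) for c, v in base.items()}
    for spec in annotation.spikes:
        gene = annotation.gene(spec.gene_id)
        iv = spike_region(spec, gene)
        f = spec.fold_change if spec.direction == "hyper" else 1.0 / spec.fold_change
        tumor_mult[iv.chrom][iv.start // bw : iv.end // bw] *= f
    return base, tumor_mult


def simulate_methylome(
    annotation: Annotation,
    config: SimulationConfig,
    seed: Optional[int] = None,
    noiseless: bool = False,
) -> tuple[list[BinTrack], TruthManifest]:
    """Draw per-sample bin-count tracks and return them with the truth.

    ``noiseless`` substitutes the model means for the negative-binomial
    draws (the infinite-count limit), with all library factors 1.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base, tumor_mult = _mean_arrays(annotation, config)

    lo, hi = config.library_factor_range
    n_samples = config.n_tumor + config.n_normal
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    if noiseless:
        factors = np.ones(n_samples)

    def draw(mult_active: bool, sample_idx: int, sample_id: str, group: str) -> BinTrack:
        data = {}
        for chrom, mu0 in base.items():
            mu = mu0 * (tumor_mult[chrom] if mult_active else 1.0)
            mu = mu * factors[sample_idx]
            if noiseless:
                data[chrom] = mu.copy()
            else:
                k = config.dispersion
                data[chrom] = rng.negative_binomial(k, k / (k + mu)).astype(float)
        return BinTrack(sample_id, config.bin_width, data, group)

    tracks = [
        draw(True, i, f"tumor_{i + 1:02d}", "tumor") for i in range(config.n_tumor)
    ] + [
        draw(False, config.n_tumor + j, f"normal_{j + 1:02d}", "normal")
        for j in range(config.n_normal)
    ]

    truth = TruthManifest(
        spikes=[
            SpikeRecord(
                s.gene_id,
                spike_region(s, annotation.gene(s.gene_id)),
                s.direction,
                s.pattern,
                s.fold_change,
                s.coupling,
            )
            for s in annotation.spikes
        ],
        biotypes={
            g.gene_id: (g.biotype, g.host_gene_id)
            for g in classify_biotypes(annotation.ncrnas, annotation.coding)
        },
    )
    for rec in truth.spikes:
        promoter = annotation.promoters[rec.gene_id].interval
        if not promoter.contains(rec.interval):
            raise ConfigConflictError(
                f"spike for {rec.gene_id} falls outside its promoter"
            )
    return tracks, truth


def simulate_expression(
    annotation: Annotation,
    truth: TruthManifest,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression coupled to the spiked methylation truth.

    Returns (lncRNA FPKM table with columns control / tumor_line_1 /
    tumor_line_2, miRNA RPM cohort matrix with tumor_* / normal_* columns).
    Silencing genes are expressed at control / fold_expression in tumor,
    activating genes at control * fold_expression; uncoupled genes get
    log-normal noise around the control level.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    coupling = {s.gene_id: s.coupling for s in truth.spikes}

    def factor(gid: str) -> float:
        c = coupling.get(gid, "none")
        if c == "silencing":
            return 1.0 / config.fold_expression
        if c == "activating":
            return config.fold_expression
        return 1.0

    lnc = [g.gene_id for g in annotation.genes if g.gene_class == "lncRNA"]
    control = rng.lognormal(np.log(10.0), 0.5, size=len(lnc))
    sd_ln = config.expression_log2_sd * np.log(2)
    cols = {"control": control}
    for line in ("tumor_line_1", "tumor_line_2"):
        noise = rng.lognormal(0.0, sd_ln, size=len(lnc))
        cols[line] = control * np.array([factor(g) for g in lnc]) * noise
    fpkm = pd.DataFrame(cols, index=pd.Index(lnc, name="gene_id"))

    mir = [g.gene_id for g in annotation.genes if g.gene_class == "miRNA"]
    base_log2 = np.log2(rng.lognormal(np.log(50.0), 0.5, size=len(mir)))
    shift = np.array([np.log2(factor(g)) for g in mir])
    samples = [f"tumor_{i + 1:02d}" for i in range(config.n_tumor)] + [
        f"normal_{j + 1:02d}" for j in range(config.n_normal)
    ]
    mat = np.empty((len(mir), len(samples)))
    for j, s in enumerate(samples):
        is_tumor = s.startswith("tumor")
        log2val = (
            base_log2
            + (shift if is_tumor else 0.0)
            + rng.normal(0.0, config.expression_log2_sd, size=len(mir))
        )
        mat[:, j] = 2.0 ** log2val
    rpm = pd.DataFrame(mat, index=pd.Index(mir, name="gene_id"), columns=samples)
    return fpkm, rpm


HISTONE_MARKS = ("H3K4me3", "H3K27me3")
HISTONE_LINES = ("control", "tumor_line_1", "tumor_line_2")


def simulate_histone_tracks(
    annotation: Annotation,
    truth: TruthManifest,
    config: SimulationConfig,
    seed: Optional[int] = None,
    noise_sd: float = 0.1,
) -> dict[tuple[str, str], BinTrack]:
    """Promoter histone-mark density tracks per cell line, on the bin grid.

    Baseline: the active mark (H3K4me3) is high across every promoter, the
    repressive mark (H3K27me3) low.  At silencing-coupled (hypermethylated)
    promoters the tumor lines lose the active mark and gain the repressive
    one by ``config.histone_fold``; activating-coupled promoters change in
    the opposite sense.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    bw = config.bin_width
    base_density = {"H3K4me3": 20.0, "H3K27me3": 2.0}
    coupling = {s.gene_id: s.coupling for s in truth.spikes}

    tracks: dict[tuple[str, str], BinTrack] = {}
    for mark in HISTONE_MARKS:
        for line in HISTONE_LINES:
            data = {
                c: np.ones(length // bw)
                for c, length in annotation.chrom_lengths.items()
            }
            for g in annotation.genes:
                piv = annotation.promoters[g.gene_id].interval
                sl = slice(piv.start // bw, piv.end // bw)
                level = base_density[mark]
                c = coupling.get(g.gene_id, "none")
                if line != "control" and c != "none":
                    silenced = c == "silencing"
                    if mark == "H3K4me3":
                        level = level / config.histone_fold if silenced else level * config.histone_fold
                    else:
                        level = level * config.histone_fold if silenced else level / config.histone_fold
                data[g.interval.chrom][sl] = level
            if noise_sd > 0:
                for c in data:
                    data[c] = data[c] * rng.lognormal(0.0, noise_sd, size=len(data[c]))
            tracks[(mark, line)] = BinTrack(f"{mark}_{line}", bw, data, None)
    return tracks


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: annotation, methylome, expression, histone.

    Returns (annotation, tracks, truth, fpkm, rpm, histone)."""
    annotation = simulate_annotation(config)
    tracks, truth = simulate_methylome(annotation, config)
    fpkm, rpm = simulate_expression(annotation, truth, config)
    histone = simulate_histone_tracks(annotation, truth, config)
    return annotation, tracks, truth, fpkm, rpm, histone
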