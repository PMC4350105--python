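"""Readers and writers for the on-disk formats of the pipeline.

Formats handled: bedGraph bin tracks (methylation and histone densities),
BED6 region sets (CGIs, polycomb regions, deletion regions), gene annotation
as BED12+1 (13th column = gene class) or GTF-lite, TSV expression tables,
TSV sample manifests, and YAML run configuration.  This module is the single
place where coordinate conventions are enforced: everything in memory is
0-based half-open; GTF 1-based starts are decremented on read.

Readers reject malformed input (off-grid records, negative values, duplicate
ids, non-numeric cells) rather than coercing it.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GENE_CLASSES, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

GROUPS = ("tumor", "normal")


class FormatError(ValueError):
    """An input file violates the expected format."""


@dataclass
class BinTrack:
    """Per-sample intensity on a fixed-width genomic bin grid.

    ``data`` maps chromosome -> dense float vector, one value per bin;
    bins absent from the source file are 0.
    """

    sample_id: str
    bin_width: int
    data: dict[str, np.ndarray] = field(default_factory=dict)
    group: Optional[str] = None

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, factor: float) -> "BinTrack":
        return BinTrack(
            self.sample_id,
            self.bin_width,
            {c: v * factor for c, v in self.data.items()},
            self.group,
        )

    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.data.values()))


@dataclass
class SampleManifest:
    """Cohort table: one (sample_id, group, path) row per sample."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_id in manifest")
        for _, group, _ in self.rows:
            if group not in GROUPS:
                raise FormatError(f"unknown group {group!r} (expected tumor/normal)")

    def count(self, group: str) -> int:
        return sum(1 for r in self.rows if r[1] == group)

    def paths(self, group: Optional[str] = None) -> list[tuple[str, str]]:
        return [(r[0], r[2]) for r in self.rows if group is None or r[1] == group]


def read_sample_manifest(path: str, require_min: int = 2) -> SampleManifest:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated columns")
            # relative track paths are taken relative to the manifest itself
            track_path = parts[2]
            if not os.path.isabs(track_path):
                track_path = os.path.join(os.path.dirname(os.path.abspath(path)), track_path)
            rows.append((parts[0], parts[1], track_path))
    manifest = SampleManifest(rows)
    for group in GROUPS:
        if manifest.count(group) < require_min:
            raise FormatError(
                f"{path}: need >= {require_min} samples in group {group}"
            )
    return manifest


def read_bin_track(
    path: str,
    bin_width: int,
    sample_id: Optional[str] = None,
    group: Optional[str] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> BinTrack:
    """Read a bedGraph whose records sit on the ``bin_width`` grid.

    If ``chrom_lengths`` is given the vectors are sized from it; otherwise
    they grow to the last observed bin per chromosome.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    max_end: dict[str, int] = {}
    n_records = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = parts[:4]
            start, end = int(start_s), int(end_s)
            if start % bin_width or end != start + bin_width:
                raise FormatError(
                    f"{path}:{ln}: record [{start},{end}) not on the "
                    f"{bin_width}-bp bin grid"
                )
            value = float(value_s)
            if value < 0:
                raise FormatError(f"{path}:{ln}: negative intensity {value}")
            per_chrom.setdefault(chrom, {})[start // bin_width] = value
            max_end[chrom] = max(max_end.get(chrom, 0), end)
            n_records += 1
    if n_records == 0:
        logger.warning("%s: empty bedGraph, track has no bins", path)
    data = {}
    lengths = chrom_lengths or max_end
    for chrom, length in lengths.items():
        vec = np.zeros(math.ceil(length / bin_width))
        for idx, value in per_chrom.get(chrom, {}).items():
            vec[idx] = value
        data[chrom] = vec
    return BinTrack(sample_id or os.path.basename(path), bin_width, data, group)


def write_bin_track(track: BinTrack, path: str, omit_zero: bool = True) -> None:
    """Write a BinTrack as bedGraph; zero bins are omitted by default."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            w = track.bin_width
            for i, value in enumerate(vec):
                if omit_zero and value == 0:
                    continue
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{value:.6g}\n")


def read_annotation(path: str, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12+1 (13th column = gene class) or GTF-lite.

    GTF-lite rows are ``gene`` features with ``gene_id`` and ``gene_class``
    attributes; their 1-based starts are converted to 0-based.
    """
    if format == "bed12":
        genes = _read_genes_bed12(path)
    elif format == "gtf_lite":
        genes = _read_genes_gtf(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _make_gene(path, ln, gene_id, chrom, start, end, strand, gene_class) -> GeneModel:
    if gene_class not in GENE_CLASSES:
        raise FormatError(f"{path}:{ln}: unknown gene_class {gene_class!r}")
    if end <= start:
        raise FormatError(f"{path}:{ln}: end {end} <= start {start}")
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), gene_class)


def _read_genes_bed12(path: str) -> list[GeneModel]:
    genes = []
    for ln, parts in _bed_rows(path, min_cols=13):
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        genes.append(
            _make_gene(path, ln, parts[3], chrom, start, end, parts[5], parts[12])
        )
    return genes


def _read_genes_gtf(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{ln}: expected 9 GTF columns")
            if parts[2] != "gene":
                continue
            attrs = {}
            for item in parts[8].rstrip(";").split(";"):
                item = item.strip()
                if item:
                    key, _, raw = item.partition(" ")
                    attrs[key] = raw.strip().strip('"')
            if "gene_id" not in attrs or "gene_class" not in attrs:
                raise FormatError(f"{path}:{ln}: missing gene_id/gene_class attribute")
            genes.append(
                _make_gene(
                    path, ln, attrs["gene_id"], parts[0],
                    int(parts[3]) - 1, int(parts[4]), parts[6], attrs["gene_class"],
                )
            )
    return genes


def write_genes_bed12(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom, str(iv.start), str(iv.end), g.gene_id, "0",
                        iv.strand, str(iv.start), str(iv.end), "0", "1",
                        str(iv.length), "0", g.gene_class,
                    ]
                )
                + "\n"
            )


def _bed_rows(path: str, min_cols: int):
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise FormatError(f"{path}:{ln}: expected >= {min_cols} columns")
            yield ln, parts


def read_regions_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file of plain regions (CGIs, polycomb, deletions)."""
    regions = []
    for ln, parts in _bed_rows(path, min_cols=3):
        start, end = int(parts[1]), int(parts[2])
        if end <= start:
            raise FormatError(f"{path}:{ln}: end {end} <= start {start}")
        strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
        regions.append(GenomicInterval(parts[0], start, end, strand))
    return regions


def write_regions_bed(regions: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_expression_table(path: str, kind: str = "fpkm_cell_lines") -> pd.DataFrame:
    """Read a gene x sample expression TSV (FPKM cell lines or RPM cohort).

    First column = gene ids, header row = sample ids.  Missing or
    non-numeric cells and duplicated gene rows are rejected.
    """
    if kind not in ("fpkm_cell_lines", "rpm_cohort"):
        raise ValueError(f"unknown expression kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated gene row {dup!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                value = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at gene {df.index[i]!r}, "
                    f"sample {col!r}: {raw!r}"
                ) from None
            if math.isnan(value):
                raise FormatError(
                    f"{path}: missing value at gene {df.index[i]!r}, sample {col!r}"
                )
            out.iloc[i, j] = value
    return out


def write_expression_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


DMR_SCORE_CAP = 300.0  # -log10(q) ceiling, avoids inf at q == 0


def write_dmr_bed(dmrs, path: str) -> None:
    """Write DMRs as BED6+3: name, -log10(min q) score (capped), strand '.',
    then direction, n_bins and max |log2 fold change| columns; coordinate
    sorted."""
    from .dmr import DMR  # local import to avoid a cycle

    rows = sorted(dmrs, key=lambda d: (d.interval.chrom, d.interval.start))
    with open(path, "w") as fh:
        for i, d in enumerate(rows):
            if d.min_q > 0:
                score = min(DMR_SCORE_CAP, -math.log10(d.min_q))
            else:
                score = DMR_SCORE_CAP
            iv = d.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tdmr_{i + 1}\t{score:.6g}\t.\t"
                f"{d.direction}\t{d.n_bins}\t{d.max_abs_log2fc:.6g}\n"
            )


def read_dmr_bed(path: str):
    """Round-trip reader for :func:`write_dmr_bed` output."""
    from .dmr import DMR

    dmrs = []
    for ln, parts in _bed_rows(path, min_cols=9):
        iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
        direction, n_bins, max_fc = parts[6], int(parts[7]), float(parts[8])
        score = float(parts[4])
        min_q = 10 ** (-score) if score < DMR_SCORE_CAP else 0.0
        dmrs.append(DMR(iv, direction, n_bins, min_q, max_fc))
    return dmrs


def load_config_yaml(path: str):
    from .sim import SimulationConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimulationConfig(**raw)


def dump_config_yaml(config, path: str) -> None:
    import dataclasses

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
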