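"""End-to-end pipeline: simulate (or load) a cohort, call DMRs, annotate
promoters, integrate expression, and write every result table to disk.

All outputs are plain text (bedGraph, BED, TSV, YAML) and deterministic
given one configuration and seed, so two runs are byte-identical.
"""

from __future__ import annotations

import os

import pandas as pd

from . import dmr as dmr_mod
from . import io as io_mod
from . import patterns as pat_mod
from . import integration as int_mod
from .sim import SimulationConfig, simulate_cohort


def run_end_to_end(config: SimulationConfig, outdir: str) -> dict:
    """Simulate a cohort and run the full analysis into ``outdir``.

    Returns the in-memory results (annotation, truth, dmrs, calls,
    patterns, candidates) for further inspection.
    """
    os.makedirs(outdir, exist_ok=True)
    annotation, tracks, truth, fpkm, rpm, histone = simulate_cohort(config)

    # raw inputs as they would arrive from disk
    io_mod.write_genes_bed12(annotation.genes, os.path.join(outdir, "genes.bed"))
    io_mod.write_regions_bed(
        [c.interval for c in annotation.cgis], os.path.join(outdir, "cgi.bed")
    )
    track_dir = os.path.join(outdir, "tracks")
    os.makedirs(track_dir, exist_ok=True)
    manifest_rows = []
    for t in tracks:
        rel = os.path.join("tracks", f"{t.sample_id}.bedgraph")
        io_mod.write_bin_track(t, os.path.join(outdir, rel))
        manifest_rows.append(f"{t.sample_id}\t{t.group}\t{rel}")
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("\n".join(manifest_rows) + "\n")
    truth.to_frame().to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    io_mod.write_expression_table(fpkm, os.path.join(outdir, "lncrna_fpkm.tsv"))
    io_mod.write_expression_table(rpm, os.path.join(outdir, "mirna_rpm.tsv"))
    io_mod.dump_config_yaml(config, os.path.join(outdir, "config.yaml"))

    # DMR calling
    dmrs, bin_stats = dmr_mod.call_dmrs(tracks)
    io_mod.write_dmr_bed(dmrs, os.path.join(outdir, "dmrs.bed"))

    # promoter calls and patterns (ncRNA promoters)
    nc_promoters = {g.gene_id: annotation.promoters[g.gene_id] for g in annotation.ncrnas}
    calls = pat_mod.map_dmrs_to_promoters(dmrs, nc_promoters)
    pattern_calls = pat_mod.classify_patterns(calls, nc_promoters, annotation.cgis, dmrs)
    pd.DataFrame(
        [
            {
                "gene_id": pc.gene_id,
                "direction": pc.direction,
                "pattern": pc.pattern,
                "pattern_name": pc.pattern_name,
                "n_dmrs": len(pc.dmr_indices),
            }
            for pc in pattern_calls
        ]
    ).to_csv(os.path.join(outdir, "calls.tsv"), sep="\t", index=False)

    # TSS profiles
    for direction in ("hyper", "hypo"):
        prof = pat_mod.tss_profile(nc_promoters, dmrs, direction)
        prof.to_frame().to_csv(os.path.join(outdir, f"profile_{direction}.tsv"), sep="\t")

    # expression integration
    meth_dirs = {
        pc.gene_id: pc.direction
        for pc in pattern_calls
        if not any(o.gene_id == pc.gene_id and o.direction != pc.direction for o in pattern_calls)
    }
    lnc_expr = int_mod.lncrna_expression_change(
        fpkm, control_cols=["control"], tumor_cols=["tumor_line_1", "tumor_line_2"]
    )
    mir_de = int_mod.mirna_differential_expression(
        rpm, {c: ("tumor" if c.startswith("tumor") else "normal") for c in rpm.columns}
    )
    mir_expr = {
        g: row["direction"] for g, row in mir_de.iterrows() if row["significant"]
    }
    expr_dirs = dict(lnc_expr[lnc_expr != "none"].items()) | mir_expr
    candidates = int_mod.call_candidates(meth_dirs, expr_dirs)
    pd.DataFrame(
        [
            {"gene_id": c.gene_id, "scenario": c.scenario,
             "methylation": c.methylation_direction, "expression": c.expression_direction}
            for c in candidates
        ]
    ).to_csv(os.path.join(outdir, "candidates.tsv"), sep="\t", index=False)

    return {
        "annotation": annotation,
        "tracks": tracks,
        "truth": truth,
        "dmrs": dmrs,
        "bin_stats": bin_stats,
        "calls": calls,
        "patterns": pattern_calls,
        "candidates": candidates,
        "fpkm": fpkm,
        "rpm": rpm,
        "histone": histone,
    }
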