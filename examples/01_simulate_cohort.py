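"""Generate a small synthetic tumor/normal methylome cohort with known truth.

The generator lays out a toy genome (coding genes, lncRNAs, pri-miRNAs with a
controlled biotype mix), places CpG islands in a fraction of promoters, and
spikes differential methylation of every CGI-context pattern class into the
tumor group at a known fold change.  The truth manifest records each spike's
region, direction, pattern and expression coupling.
"""

from ncmeth import SimulationConfig, simulate_annotation, simulate_methylome

config = SimulationConfig(
    n_chrom=1, chrom_length=1_000_000, n_coding=20, n_lncrna=20, n_mirna=10,
    n_tumor=10, n_normal=10, seed=1,
)
annotation = simulate_annotation(config)
tracks, truth = simulate_methylome(annotation, config)

print(f"genome: {config.n_chrom} x {config.chrom_length:,} bp, "
      f"{config.chrom_length // config.bin_width:,} bins of {config.bin_width} bp")
print(f"genes: {len(annotation.coding)} coding, {len(annotation.ncrnas)} ncRNA; "
      f"{len(annotation.cgis)} promoter CGIs")
print(f"cohort: {config.n_tumor} tumor + {config.n_normal} normal samples, "
      f"NB(mean {config.baseline_mean:g}, dispersion {config.dispersion:g})")
print("\nspiked truth (gene, pattern, direction, fold, coupling):")
for s in truth.spikes:
    print(f"  {s.gene_id:>9}  pattern {s.pattern}  {s.direction:>5}  "
          f"x{s.fold_change:g}  {s.coupling}")
# Each spike multiplies (hyper) or divides (hypo) the tumor-group mean over
# the region its pattern dictates; everything else is shared baseline noise.
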