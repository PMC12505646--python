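"""Generate a synthetic crop-vs-wild diploid SNP panel with known sweeps.

Builds the packaged six-lineage configuration (two wild sea-beet-like
populations, four cultivated lineages bottlenecked off the Mediterranean-like
stock, three shared 100 kb hard sweeps in the root-crop lineages), writes
VCF + popmap + GFF3 + truth BED into ./scratch_fixture, and prints what was
made.  Identical seeds give byte-identical files.
"""

import sweepscan as ss

cfg = ss.beet_panel_config(seed=42)
paths = ss.emit_fixture(cfg, "scratch_fixture")

table, popmap, truth = ss.simulate(cfg)
print(f"panel: {table.n_samples} samples x {table.n_sites} SNPs "
      f"over {sum(cfg.chromosomes.values())/1e6:.0f} Mb")
for pop in sorted(popmap.labels()):
    print(f"  {pop:9s} n={len(popmap.samples_for(pop))}")
print("truth sweep intervals (sugar):", truth.sweep_regions["sugar"].intervals)
for kind, p in paths.items():
    print(f"wrote {kind}: {p}")
# The truth BED is the ground truth a sweep caller should recover; every
# other file is a standard input a real resequencing study would provide.
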