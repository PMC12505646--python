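# sweepscan

Domestication-sweep scanning for diploid SNP panels: the crop-versus-wild
genome-scan toolkit used to find selection footprints in resequencing
studies of crops such as beet (*Beta vulgaris*), where cultivated lineages
(sugar, table, fodder, leaf types) are compared against their wild sea-beet
relatives.

It is a library first (everything importable from `sweepscan`), with an
`examples/` directory of short narrative scripts and a thin `sweepscan`
command-line wrapper for the common pipeline steps.

## What it computes

Given a multi-sample VCF, a sample→lineage popmap and a GFF3 of gene
models, the package provides:

- **Variant filtering** — GATK-style hard filters (`QD < 2.0 || FS > 60.0 ||
  MQ < 40.0 || SOR > 3.0 || MQRankSum < -12.5 || ReadPosRankSum < -8.0`),
  per-genotype depth masking (depth outside [2, 50] → missing), then
  site-level missingness ≤ 10%, MAF > 5% and mean depth > 5.
- **Nucleotide diversity (π)** — per-site unbiased heterozygosity
  2·c₀·c₁/(n(n−1)) summed over variant sites per window and divided by the
  window length (10 kb windows, 1 kb step), per lineage; plus per-sample
  observed heterozygosity and the inbreeding coefficient
  F = (O_hom − E_hom)/(N − E_hom).
- **Weir–Cockerham F_ST** — per-site variance components a (among
  populations), b (among individuals), c (within individuals) for r = 2;
  windowed mean of a/(a+b+c) and the genome-wide pair
  (mean F_ST, weighted F_ST = Σa/Σ(a+b+c)).
- **Linkage disequilibrium** — composite genotype r² (squared Pearson
  correlation of dosages), decay curves binned in 100 bp distance bins with
  the half-max-distance summary, and greedy LD pruning (10 kb window, one-SNP
  step, r² > 0.5).
- **XP-CLR** — a cross-population composite likelihood ratio scan.  Under
  neutrality the object population's frequency is modelled as
  Normal(p_R, ω·p_R(1−p_R)) truncated to (0,1) with boundary point masses,
  where ω is a genome-wide drift variance estimated by moments.  Under
  hitchhiking a site at map distance r escapes the sweep with probability
  c = 1 − exp(−r·ln(2Ns)/s) and otherwise rides its allele to fixation.
  The score is 2·max over an s-grid of the LD-down-weighted
  log-likelihood-ratio sum per grid point (0.005 Morgan windows, ≤ 200 SNPs,
  1 kb grid, p0 = 0.95).
- **Composite sweep caller** — empirical top-5% regions of XP-CLR and
  windowed F_ST, intersected and merged (bedtools-style semantics), with
  per-chromosome length/count summaries, ≥ 1 bp gene intersection,
  multi-lineage shared/specific gene counts, and a π-contrast screen
  (cultivated π in its lowest 5% while wild π at or above its median).
- **Structure** — genotype PCA (mean-imputed, √(2p(1−p))-scaled) and a
  neighbor-joining tree from p-distances with bootstrap supports and
  outgroup rooting.
- **Synthetic panels** — a seeded Balding–Nichols generator with a
  population tree, domestication bottlenecks, inbreeding, missingness,
  read depths, distance-decaying LD and localized hard sweeps with known
  truth intervals, emitted as VCF/popmap/GFF3/BED.

## Worked example

Scan a simulated population pair with one hard sweep
(`python examples/03_xpclr_scan.py`):

```
drift variance omega = 0.530 (from 5737 informative sites)
mean XP-CLR score inside the sweep:    127.96
mean XP-CLR score outside the sweep:     0.00
peak score at 302 kb (sweep centre simulated at 300 kb)
```

The object population was simulated with a selective sweep (s = 0.05)
centred at 300 kb: the likelihood ratio is essentially zero across the
neutral background and two orders of magnitude higher across the swept
interval, peaking 2 kb from the true target.

Running the full composite caller on the packaged six-lineage fixture
(`python examples/04_call_sweeps.py`) prints:

```
called sweep regions (top-5% overlap of both scans, merged):
chrom  total_bp  max_bp  avg_bp  n_sweeps
 chr1    218000  110000  109000         2
 chr2    110000  110000  110000         1
truth recall: 100.0% of 300003 swept bp
33 candidate genes intersect the called regions (first 3: ['gene_chr1_0070', 'gene_chr1_0071', 'gene_chr1_0072'])
```

All three simulated 100 kb sweeps are recovered in full, with no called
base pairs outside the swept neighbourhoods, and the caller reports the
genes they contain.

The CLI mirrors the same steps, e.g.

```sh
sweepscan simulate --seed 42 -o fixtures/
sweepscan fst --vcf fixtures/panel.vcf --popmap fixtures/popmap.tsv \
    --pop-a sugar --pop-b med_wild --out fst.csv
sweepscan xpclr --vcf fixtures/panel.vcf --popmap fixtures/popmap.tsv \
    --object sugar --ref med_wild --out xpclr.csv
sweepscan call-sweeps --xpclr xpclr.csv --fst fst.csv \
    --gff fixtures/genes.gff3 --out-bed sweeps.bed --out-genes genes.txt
```

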