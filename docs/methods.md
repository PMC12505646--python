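# Methods

This note documents the statistical models, the defaults that matter, the
numerical choices, and what the synthetic-data generator does and does not
emulate.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Filtering

Variant filtering mirrors the standard GATK→VCFtools order.  Hard filters
are strict inequalities on per-site INFO annotations (a site is removed
when any criterion fires); an absent annotation passes its criterion, the
GATK convention for missing values, and every removal is logged per
criterion.  Genotype-level depth masking (depth outside [2, 50] → missing)
happens *before* site-level filters, so a site's missingness and MAF are
computed on the depth-masked matrix.  MAF uses non-missing dosages only and
the threshold is strict (a site at exactly 5% is removed).  Filters are
idempotent; re-filtering after subsetting samples is the composable path
(`table.take_samples(...)` followed by `apply_site_filters`) rather than a
flag, because a MAF/missingness filter is only meaningful relative to the
panel it is computed on and the explicit call makes that panel visible at
the call site.

INDELs are carried with a type flag; scans operate on SNPs
(`table.snps_only()`), the conservative default since INDEL dosages have no
comparable error model.  Multiallelic records are skipped with a warning.

## Diversity and inbreeding

Per-site π is the unbiased estimator 2·c₀·c₁/(n(n−1)) over the n non-missing
alleles of the lineage under study (per-subpopulation allele counts).
Windowed π sums variant-site values and divides by window length, so
monomorphic positions contribute zero — the windowed-π convention of
VCFtools.  Windows are 10 kb with a 1 kb step (overlapping) by default;
a non-overlapping scan is `step == window`.  Terminal partial windows are
emitted, divided by their actual length, and flagged `partial`.  Windows
with no variants have value 0 (they are genuinely monomorphic stretches,
not missing data), so lineage averages include them.

The inbreeding coefficient per sample is F = (O_hom − E_hom)/(N − E_hom)
with E_hom summed per site as 1 − 2p(1−p)·2n/(2n−1) (p the panel-wide
alternate frequency, n the panel-wide non-missing diploid count) — the
per-site form used by VCFtools `--het`.  Note the 2n/(2n−1) factor belongs
in E_hom (expected homozygosity given the sample), not in the sampling
expectation of per-site π, whose unbiased estimator already has expectation
exactly 2p(1−p) under binomial sampling.

p-distance between two samples is mean |dosage_i − dosage_j|/2 over sites
non-missing in both; pairs sharing fewer than 100 sites are flagged
unreliable, and a pair with zero shared sites is an error unless the caller
opts into NaN entries.

## Weir–Cockerham F_ST

The r = 2 specialization of the 1984 variance-component estimator, from
per-population sample sizes, allele frequencies and observed heterozygote
proportions.  Per-site ratios a/(a+b+c) may be negative and are retained
(matching VCFtools); "mean F_ST" averages per-site ratios while "weighted
F_ST" is Σa/Σ(a+b+c), and both are always reported because the weighted
form is the consistent genome-wide estimator while the mean is what the
window track averages.  Sites monomorphic across both populations, or with
an entirely missing population, are skipped and counted — never imputed.

## LD

r² is the composite genotype measure: squared Pearson correlation of dosage
vectors over pairwise-complete samples.  It needs no phasing (the input
panels are unphased), is deterministic, and is invariant to allele
relabeling.  Decay curves bin all intra-chromosomal pairs within 500 kb
into 100 bp bins; "max r²" is the maximum *binned mean* (a single perfect
pair would otherwise dominate), and the half-max distance is the first bin
beyond the maximum's bin whose mean drops to ≤ max/2, reported as a
[start, end) bp interval.  Optional seeded reservoir subsampling caps pairs
per bin for large panels (off by default).  Pruning is a greedy
left-to-right scan: a SNP is dropped when r² > 0.5 with any retained SNP at
most 10 kb behind it, which guarantees the advertised postcondition and is
verified by exhaustive pair checking in the tests.

## XP-CLR

The scan asks, for every grid point, whether the object population's
allele-frequency configuration around that point is better explained by
neutral drift from the reference or by hitchhiking on a selected allele at
the point.

*Neutral model.*  Given reference frequency p_R, the object frequency is
Normal(p_R, ω·p_R(1−p_R)) truncated to (0,1), with the truncated tail mass
placed as point masses at 0 and 1 (drift to fixation).  ω is the
genome-wide drift-variance scale, estimated by moments over sites with a
polymorphic reference sample:
ω̂ = mean[((p_O − p_R)² − p_R(1−p_R)(1/(2n_O) + 1/(2n_R))) / (p_R(1−p_R))],
floored at 10⁻⁶; the subtraction removes binomial sampling noise, which
makes ω̂ invariant to sample size (tested).  Fewer than 500 informative
sites is an error — the calibration is too unstable to scan with.

*Sweep model.*  A site at map distance r (Morgans) from the swept point
escapes the sweep with probability c = 1 − exp(−r·ln(2Ns)/s), clipped to
[0,1] and set to 1 when 2Ns ≤ 1; with probability 1 − c it hitchhikes to
fixation of whichever allele rode the selected haplotype (probability p_R
for the alternate).  The sweep likelihood is therefore the mixture
c·L_neutral + (1−c)·[p_R·1{k=2n} + (1−p_R)·1{k=0}] — a star-like
approximation of the post-sweep frequency distortion.  The model nests
neutrality (c → 1), so the score, 2·max over a 12-point log-spaced s-grid
in [10⁻⁴, 0.5] of the weighted LLR sum, is non-negative by construction.

*Weights.*  SNPs within a window are clustered by single linkage on
pairwise r² > p0 (default 0.95) computed in the reference population, each
SNP weighted 1/(cluster size).  The scan forms clusters once per chromosome
testing links within a 30-SNP neighbour span (clusters above such a high
threshold are physically local), which the tests cross-check against an
independent union-find.

*Windows.*  Grid points every 1 kb; window = SNPs within ±0.0025 Morgans on
a uniform map (default 1 cM/Mb, configurable), truncated to the 200 nearest
SNPs.  Effective size N defaults to 10,000.  For track-style plots the grid
scores are rebinned to 10 kb/1 kb windows by max-score-in-window.

*Integration.*  The neutral integral ∫ Binom(k|2n,x)·f_N(x) dx uses
composite Gauss–Legendre with a fixed 512-node budget, with panel breaks at
the integrand's sharp features (the ±8σ band of the drift density and the
±8 s.d. band of the binomial around k/2n).  A fixed uniform trapezoid was
rejected: its O(h²) error at 512 nodes is ~10⁻⁴ for small ω or near-fixed
counts, while the panelled Gauss–Legendre agrees with a 10,000-node
refinement to ~10⁻¹². Likelihoods are floored at 10⁻³⁰⁰ before logs.

## Composite sweep caller

Thresholds are empirical nearest-rank percentiles (the ⌈q·n⌉-th order
statistic) over defined windows, computed genome-wide rather than
per-chromosome (the scan figures such thresholds are drawn as one line per
genome), with inclusive selection so ties never empty the top slice.
Selected windows are unioned; two scans' region sets are intersected
base-pair-wise and merged with bedtools semantics (book-ended intervals
join at gap 0).  Gene intersection uses the standard ≥ 1 bp rule.  The
π-contrast screen selects windows where every cultivated lineage's π is at
or below its own 5% quantile while the wild lineage's π is at or above its
median; the two quantiles are this module's own defaults, exposed in the
API and echoed in output labels, since "exceptionally low/high" has no
canonical quantification.  All interval operations are verified against
brute-force per-bp bitmaps in the tests.

## PCA and NJ

PCA mean-imputes missing dosages, centers per site and scales by
√(2p̂(1−p̂)), then eigendecomposes the sample–sample covariance; sites with
zero post-imputation variance are dropped and counted.  Mean imputation is
the simplest standard choice for genotype PCA; it shrinks coordinates of
high-missingness samples toward the origin, which is acceptable at the
≤ 10% missingness the filters guarantee.

NJ is the Saitou–Nei agglomeration with the standard Q criterion and a
deterministic lowest-index tie-break.  Negative branch lengths are clamped
to 0 with the deficit transferred to the sibling edge (common practice; a
raw mode exists).  Bootstrap resamples sites with replacement, rebuilds
p-distance + NJ per replicate, and annotates each internal edge of the
full-data tree with the percentage of replicates containing its
bipartition.  Rooting flattens the tree to an edge graph (suppressing any
degree-2 node left by a previous rooting), places the root at the midpoint
of the outgroup's pendant edge, and rebuilds — so rooting is idempotent,
conserves leaf-to-leaf path lengths exactly, and carries bootstrap values
with their edges (support is a bipartition property, not a node property).
Newick I/O goes through Bio.Phylo with 17-significant-digit branch lengths
so round-trips preserve lengths to 10⁻⁹.

## Synthetic panels

The generator exists to give every stage input with known truth, at the
same statistical structure the pipeline assumes: a population tree with
Balding–Nichols drift (branch F turns parent frequency p into
Beta(p(1−F)/F, (1−p)(1−F)/F)), per-population inbreeding
(P(het) = 2p(1−p)(1−F_is)), Bernoulli missingness, Poisson read depths
(with depth < 2 emitted as missing so the depth filter has work to do),
and hard sweeps that push post-drift frequencies toward fixation with the
same escape-probability kernel the XP-CLR sweep model assumes.  That
kernel sharing is deliberate and documented as the favorable case: it makes
detectability a property of (s, N, map) rather than of kernel mismatch, and
the caller is additionally exercised through the F_ST and π-contrast paths,
which assume no kernel at all.

LD is induced at the haplotype level: each haplotype carries a latent
Gaussian whose correlation between sites decays as exp(−d/ℓ) (an AR(1) in
physical distance, ℓ = 2 kb by default); the allele at a site is the latent
quantile thresholded at the site's population frequency.  Marginal
frequencies are exact, and genotype r² decays smoothly with distance —
preferred over a block lattice because the decay-curve semantics can then
be checked against a smooth fitted curve rather than a step function.

What the generator does **not** emulate: recombination-driven haplotype
mosaics and coalescent ancestry (frequencies are drawn, not evolved),
site-frequency-spectrum skews from demography, variable mutation rate,
genotyping error beyond depth-driven missingness, and INDELs.  Passing
tests therefore demonstrate that the estimators recover the parameters of
this model at desk scale, not that the pipeline is robust to every property
of real resequencing data.

The packaged fixture (`beet_panel_config`, seed 42) has six lineages with
the study panel's sample sizes (53 + 18 wild, 71 + 44 + 30 + 29 cultivated),
branch drifts placing crop–wild differentiation in the 0.02–0.15 range,
two 3 Mb chromosomes at 10 SNPs/kb (60,000 SNPs), and three shared 100 kb
sweeps (s = 0.05) in the root-crop lineages.  Two 3 Mb chromosomes keep the
fixture desk-scale while leaving the 300 kb of truth at exactly 5% of the
genome — the largest fraction a top-5% composite caller can recover in
full, which is what makes recall a meaningful score for it.  Calibration
panels elsewhere in the tests use two populations at F = 0.10, 50 + 50
samples and 20,000 SNPs (F_ST recovery), 50 samples × 10,000 SNPs at
F_is = 0.3 (inbreeding recovery), and twenty 600 kb single-sweep replicates
(power/null calibration).

All draws flow from one `numpy` Generator seeded by the config, and fixture
emission is byte-deterministic under a fixed seed.

## Pipeline and reporting

Percentages round half-up to one decimal and always carry their
denominator, so a class share can never silently switch reference totals.
The positional variant classifier uses precedence CDS > gene body (intron
proxy) > 5 kb flank (up/downstream) > intergenic; 5 kb is the common
annotation default for flank distance.  Coding consequences are computed
only when a CDS model with sequence is supplied (single-exon model,
standard genetic code via Biopython).  `run_pipeline` executes
filter → π/F_ST/XP-CLR → LD → structure → sweep calling, writes every
artifact plus a manifest with config echo and SHA-256 checksums, aborts
with a stage-named error on failure, and reproduces identical checksums on
identical inputs.  Its bootstrap count defaults to 0 (the NJ tree is still
written); `bootstrap_support` itself defaults to 100 replicates.

## Known limitations

- The XP-CLR sweep kernel is the star-like approximation, not the original
  method's post-sweep density; scores are comparable within a scan but not
  numerically to other implementations.
- The uniform genetic map makes Morgan windows proportional to bp windows;
  a real map would change window membership near recombination hotspots.
- The WC84 estimator is pairwise only (r = 2); no multi-population or
  haplotype-based F_ST.
- Neutral XP-CLR scores are frequently exactly 0 (the maximum over s is
  floored at the nested neutral case), so the neutral score distribution is
  a point mass plus a tail; percentile thresholds on XP-CLR tracks are only
  informative when a real signal puts more than the top quantile above 0.
- p-distance treats dosage differences as evolutionary distance; it is a
  crude clock under inbreeding differences between lineages.
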