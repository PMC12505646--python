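"""Seeded synthetic diploid SNP panels with population structure, a
domestication bottleneck, inbreeding, missingness, read depths, linkage
disequilibrium and localized hard sweeps.

Allele frequencies evolve along a population tree under the
Balding-Nichols model: a branch with drift F turns parent frequency p into
Beta(p(1-F)/F, (1-p)(1-F)/F).  Within the sweep interval of a cultivated
population the post-drift frequency is pushed toward fixation of a chosen
allele with the same escape-probability kernel the XP-CLR scan assumes, so
simulated sweeps are model-consistent and detectability is a property of
the parameters, not of kernel mismatch.

LD is induced at the haplotype level: each haplotype carries a latent
Gaussian process whose correlation between sites decays as
exp(-distance/ld_scale_bp); the allele at a site is the latent quantile
thresholded at the site's population frequency, so marginal frequencies
are exact while genotype r^2 decays smoothly with distance.

Identical config + seed reproduces byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr

from .io import MISSING, GenotypeTable, PopulationMap, write_bed, write_popmap, write_vcf
from .sweeps import RegionSet
from .xpclr import escape_probability


@dataclass
class SweepSpec:
    """A hard sweep: ``population`` swept around ``center`` on ``chrom``
    with truth interval center +- half_width and selection coefficient s."""

    population: str
    chrom: str
    center: int
    half_width: int
    s: float


@dataclass
class PopulationSpec:
    """One node of the population tree (parent None = ancestral root).

    ``f_branch`` is the Balding-Nichols drift along the branch from the
    parent; ``n_samples`` is 0 for unsampled internal nodes; ``f_is`` is the
    within-population inbreeding coefficient.
    """

    label: str
    parent: str | None
    f_branch: float = 0.0
    n_samples: int = 0
    f_is: float = 0.0


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    chromosomes: dict[str, int]
    snp_per_kb: float = 10.0
    #: ancestral frequency law: Beta(a, b), or None for Uniform[0.05, 0.95]
    ancestral_beta: tuple[float, float] | None = None
    missing_rate: float = 0.02
    mean_depth: float = 12.0
    sweeps: list[SweepSpec] = field(default_factory=list)
    rate_cm_per_mb: float = 1.0
    effective_n: float = 10_000.0
    ld_scale_bp: float = 2_000.0
    seed: int = 0

    def __post_init__(self):
        labels = {p.label for p in self.populations}
        for p in self.populations:
            if not (0.0 <= p.f_branch < 1.0):
                raise ValueError(f"f_branch out of [0,1) for {p.label}")
            if not (0.0 <= p.f_is <= 1.0):
                raise ValueError(f"f_is out of [0,1] for {p.label}")
            if p.parent is not None and p.parent not in labels:
                raise ValueError(f"unknown parent {p.parent!r} of {p.label}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate out of range")
        for sw in self.sweeps:
            if sw.chrom not in self.chromosomes:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom}")
            clen = self.chromosomes[sw.chrom]
            if sw.center - sw.half_width < 1 or sw.center + sw.half_width > clen:
                raise ValueError("sweep interval outside chromosome bounds")
            if sw.population not in labels:
                raise ValueError(f"sweep in unknown population {sw.population}")

    def sampled(self) -> list[PopulationSpec]:
        return [p for p in self.populations if p.n_samples > 0]


@dataclass
class SimTruth:
    """Realized per-population frequencies plus the sweep truth intervals."""

    chrom: np.ndarray
    pos: np.ndarray
    freqs: dict[str, np.ndarray]
    sweep_regions: dict[str, RegionSet]


def _topological(pops: list[PopulationSpec]) -> list[PopulationSpec]:
    by_label = {p.label: p for p in pops}
    order, seen = [], set()

    def visit(p):
        if p.label in seen:
            return
        if p.parent is not None:
            visit(by_label[p.parent])
        seen.add(p.label)
        order.append(p)

    for p in pops:
        visit(p)
    return order


def _drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    if f == 0.0:
        return p.copy()
    pc = np.clip(p, 1e-9, 1 - 1e-9)
    scale = (1.0 - f) / f
    return rng.beta(pc * scale, (1.0 - pc) * scale)


def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimTruth:
    """Draw site positions, ancestral frequencies, per-branch drift and the
    sweep frequency distortion; returns realized frequencies + truth."""
    rng = rng or np.random.default_rng(config.seed)
    chroms, poss = [], []
    for c in config.chromosomes:  # insertion order: deterministic
        clen = config.chromosomes[c]
        n_sites = int(round(clen / 1000.0 * config.snp_per_kb))
        pos = np.sort(rng.choice(clen, size=n_sites, replace=False)) + 1
        chroms.append(np.full(n_sites, c, dtype=object))
        poss.append(pos.astype(np.int64))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    L = len(pos)
    if config.ancestral_beta is None:
        p0 = rng.uniform(0.05, 0.95, size=L)
    else:
        a, b = config.ancestral_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        p0 = rng.beta(a, b, size=L)
    freqs: dict[str, np.ndarray] = {}
    for popspec in _topological(config.populations):
        parent = p0 if popspec.parent is None else freqs[popspec.parent]
        freqs[popspec.label] = _drift(parent, popspec.f_branch, rng)
    m_per_bp = config.rate_cm_per_mb * 1e-8
    sweep_regions: dict[str, list] = {}
    for sw in config.sweeps:
        in_iv = (chrom == sw.chrom) & (np.abs(pos - sw.center) <= sw.half_width)
        idx = np.flatnonzero(in_iv)
        p = freqs[sw.population]
        r = np.abs(pos[idx] - sw.center) * m_per_bp
        c = escape_probability(r, sw.s, config.effective_n)
        ride_alt = rng.random(len(idx)) < p[idx]  # allele on the swept haplotype
        p_new = np.where(ride_alt, 1.0 - c * (1.0 - p[idx]), c * p[idx])
        p[idx] = p_new
        sweep_regions.setdefault(sw.population, []).append(
            (sw.chrom, sw.center - sw.half_width, sw.center + sw.half_width)
        )
    regions = {
        pop: RegionSet(ivs, label=f"truth:{pop}").merged()
        for pop, ivs in sweep_regions.items()
    }
    return SimTruth(chrom, pos, freqs, regions)


def sample_genotypes(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeTable:
    """Draw diploid genotypes with LD, inbreeding, missingness and depths.

    Per haplotype, a latent AR(1)-in-distance Gaussian process supplies
    correlated uniform quantiles; an individual's second haplotype copies
    the first at a site with probability f_is, giving
    P(het) = 2p(1-p)(1-f_is).  Depth is Poisson(mean_depth); genotypes with
    depth < 2 are emitted as missing (so downstream depth filters have work
    to do), and an extra Bernoulli(missing_rate) mask drops genotype and
    depth together.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    sampled = config.sampled()
    sample_ids = [
        f"{p.label}_{i:03d}" for p in sampled for i in range(1, p.n_samples + 1)
    ]
    L = len(truth.pos)
    dosage = np.empty((len(sample_ids), L), dtype=np.int8)
    depth = np.empty_like(dosage, dtype=np.int32)
    row = 0
    for popspec in sampled:
        n = popspec.n_samples
        p_pop = truth.freqs[popspec.label]
        alleles = np.empty((2 * n, L), dtype=bool)
        for c in config.chromosomes:
            idx = np.flatnonzero(truth.chrom == c)
            pos_c = truth.pos[idx]
            m = len(idx)
            z = np.empty((2 * n, m))
            z[:, 0] = rng.standard_normal(2 * n)
            rho = np.exp(-np.diff(pos_c) / config.ld_scale_bp)
            eps = rng.standard_normal((2 * n, m - 1))
            for j in range(1, m):
                r = rho[j - 1]
                z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j - 1]
            alleles[:, idx] = ndtr(z) < p_pop[idx][None, :]
        a1 = alleles[0::2]
        a2 = alleles[1::2]
        if popspec.f_is > 0:
            ibd = rng.random((n, L)) < popspec.f_is
            a2 = np.where(ibd, a1, a2)
        dosage[row : row + n] = a1.astype(np.int8) + a2.astype(np.int8)
        row += n
    depth[:] = rng.poisson(config.mean_depth, size=dosage.shape)
    dosage[depth < 2] = MISSING
    miss = rng.random(dosage.shape) < config.missing_rate
    dosage[miss] = MISSING
    depth[miss] = MISSING
    # plausible passing INFO annotations so hard filters are exercised
    info = {
        "QD": np.round(rng.uniform(10.0, 35.0, size=L), 2),
        "FS": np.round(rng.uniform(0.0, 10.0, size=L), 3),
        "MQ": np.round(rng.uniform(50.0, 60.0, size=L), 2),
    }
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref_i = rng.integers(0, 4, size=L)
    alt_i = (ref_i + rng.integers(1, 4, size=L)) % 4
    return GenotypeTable(
        sample_ids=sample_ids,
        chrom=truth.chrom,
        pos=truth.pos,
        ref=bases[ref_i],
        alt=bases[alt_i],
        dosage=dosage,
        depth=depth,
        info=info,
        is_snp=np.ones(L, dtype=bool),
        contig_lengths=dict(config.chromosomes),
    )


def simulate(config: SimConfig) -> tuple[GenotypeTable, PopulationMap, SimTruth]:
    """Frequencies + genotypes + popmap in one call (seeded by the config)."""
    truth = simulate_frequencies(config)
    table = sample_genotypes(truth, config)
    assignments = {}
    for p in config.sampled():
        for i in range(1, p.n_samples + 1):
            assignments[f"{p.label}_{i:03d}"] = p.label
    return table, PopulationMap(assignments), truth


def _write_gff(config: SimConfig, path: Path) -> None:
    """Genes tiled every 10 kb (2 kb long) so interval logic has targets."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c, clen in config.chromosomes.items():
            k = 0
            start = 1
            while start + 1999 <= clen:
                gid = f"gene_{c}_{k:04d}"
                fh.write(
                    f"{c}\tsim\tgene\t{start}\t{start + 1999}\t.\t+\t.\tID={gid}\n"
                )
                k += 1
                start += 10_000


def emit_fixture(config: SimConfig, outdir) -> dict[str, Path]:
    """Write VCF + popmap + GFF3 + truth BED + config echo into ``outdir``.

    Identical config and seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, popmap, truth = simulate(config)
    paths = {
        "vcf": outdir / "panel.vcf",
        "popmap": outdir / "popmap.tsv",
        "gff": outdir / "genes.gff3",
        "truth_bed": outdir / "truth_sweeps.bed",
        "config": outdir / "config.json",
    }
    write_vcf(table, paths["vcf"])
    write_popmap(popmap, paths["popmap"])
    _write_gff(config, paths["gff"])
    with open(paths["truth_bed"], "w") as fh:
        for pop in sorted(truth.sweep_regions):
            for chrom, s, e in truth.sweep_regions[pop].intervals:
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{pop}\n")
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Canned configurations


def beet_panel_config(seed: int = 42) -> SimConfig:
    """The packaged fixture: six beet-like lineages (two wild, four
    cultivated, bottlenecked off the Mediterranean-like wild stock), two
    chromosomes, and three shared domestication sweeps (s = 0.05) in the
    root-crop lineages.

    Sample sizes follow the study panel; branch drifts are set so pairwise
    differentiation against the wild reference falls in the 0.02-0.15 range
    typical of crop-wild beet comparisons.  The 6 Mb genome keeps a
    desk-scale runtime while leaving the 3 x 100 kb truth at 5% of the
    genome, the fraction the top-5% composite caller can recover.
    """
    pops = [
        PopulationSpec("ancestral", None, 0.0, 0),
        PopulationSpec("med_wild", "ancestral", 0.02, 53),
        PopulationSpec("atl_wild", "ancestral", 0.09, 18, f_is=0.05),
        PopulationSpec("sugar", "med_wild", 0.09, 71, f_is=0.10),
        PopulationSpec("table", "med_wild", 0.10, 44, f_is=0.10),
        PopulationSpec("fodder", "med_wild", 0.05, 30, f_is=0.05),
        PopulationSpec("leaf", "med_wild", 0.02, 29),
    ]
    chroms = {"chr1": 3_000_000, "chr2": 3_000_000}
    centers = [("chr1", 750_000), ("chr1", 2_250_000), ("chr2", 1_500_000)]
    sweeps = [
        SweepSpec(pop, c, center, 50_000, 0.05)
        for pop in ("sugar", "table", "fodder")
        for c, center in centers
    ]
    return SimConfig(
        populations=pops,
        chromosomes=chroms,
        snp_per_kb=10.0,
        missing_rate=0.02,
        mean_depth=12.0,
        sweeps=sweeps,
        seed=seed,
    )


def two_population_config(
    f: float = 0.10,
    n_samples: int = 50,
    chrom_len: int = 2_000_000,
    snp_per_kb: float = 10.0,
    f_is: float = 0.0,
    sweep: SweepSpec | None = None,
    seed: int = 0,
) -> SimConfig:
    """Object + reference populations, each drifted F from a shared ancestor
    (so Weir-Cockerham F_ST between them estimates that F)."""
    pops = [
        PopulationSpec("ancestral", None, 0.0, 0),
        PopulationSpec("ref_pop", "ancestral", f, n_samples),
        PopulationSpec("obj_pop", "ancestral", f, n_samples, f_is=f_is),
    ]
    return SimConfig(
        populations=pops,
        chromosomes={"chr1": chrom_len},
        snp_per_kb=snp_per_kb,
        missing_rate=0.0,
        mean_depth=30.0,
        sweeps=[sweep] if sweep else [],
        seed=seed,
    )
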