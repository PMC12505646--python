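"""Cross-population composite likelihood ratio (XP-CLR) sweep scan.

The scan contrasts two models for the allele frequency of an *object*
population (e.g. a cultivated lineage) given the frequency observed in a
*reference* population (its wild relative):

* neutral drift — the object frequency is Normal(p_R, omega * p_R(1-p_R))
  truncated to (0,1) with the tail mass placed as point masses at 0 and 1,
  where omega is a genome-wide drift-variance scale estimated by moments;
* hitchhiking — with probability (1-c) a linked neutral site rides the
  selected haplotype to fixation of whichever allele it carried, and with
  probability c it escapes by recombination and drifts as under neutrality.
  The escape probability is c = 1 - exp(-r * ln(2Ns)/s) for map distance r
  (Morgans) to the sweep target, selection coefficient s and effective size
  N — a star-like approximation of the post-sweep frequency distortion.

Scores are 2 * max over an s-grid of the weighted sum of per-SNP
log-likelihood differences, floored at 0; SNPs in near-perfect LD within a
window are down-weighted by 1/(cluster size) of their single-linkage
r^2 > p0 cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .diversity import WindowTrack, chromosome_lengths, window_grid
from .io import MISSING, GenotypeTable, PopulationMap
from .ld import _r2_one_vs_many

_LOG_TINY = 1e-300

_LEGGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss_cached(deg: int) -> tuple[np.ndarray, np.ndarray]:
    if deg not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[deg] = np.polynomial.legendre.leggauss(deg)
    return _LEGGAUSS_CACHE[deg]


def _default_s_grid() -> tuple[float, ...]:
    return tuple(np.logspace(np.log10(1e-4), np.log10(0.5), 12))


@dataclass
class XpclrConfig:
    """Scan parameters (defaults mirror common usage: 0.005 Morgan windows,
    200 SNPs max, 1 kb grid, p0 = 0.95)."""

    window_morgans: float = 0.005
    max_snps: int = 200
    grid_bp: int = 1_000
    p0: float = 0.95
    s_grid: tuple[float, ...] = field(default_factory=_default_s_grid)
    effective_n: float = 10_000.0
    rate_cm_per_mb: float = 1.0
    #: neighbour span (in SNPs) within which the scan tests r^2 > p0 links
    #: when forming down-weighting clusters chromosome-wide
    cluster_span_snps: int = 30

    def __post_init__(self):
        if not (0 < self.p0 <= 1):
            raise ValueError("p0 must be in (0, 1]")
        if len(self.s_grid) == 0:
            raise ValueError("empty selection-coefficient grid")
        for name in ("window_morgans", "max_snps", "grid_bp", "effective_n",
                     "rate_cm_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def morgans_per_bp(self) -> float:
        return self.rate_cm_per_mb * 1e-8


@dataclass
class DriftVariance:
    """Genome-wide variance scale of object-population frequency drift
    relative to the reference (omega > 0)."""

    omega: float
    n_sites: int = 0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")


def escape_probability(r_dist, s: float, effective_n: float):
    """Probability a site at map distance ``r_dist`` (Morgans) recombines off
    the selected haplotype during a sweep of strength ``s``; clipped to
    [0, 1], and 1 (no sweep effect) when 2Ns <= 1."""
    r = np.asarray(r_dist, dtype=float)
    two_ns = 2.0 * effective_n * s
    if two_ns <= 1.0:
        return np.ones_like(r)
    return np.clip(1.0 - np.exp(-r * np.log(two_ns) / s), 0.0, 1.0)


def _pop_freq_counts(table: GenotypeTable, samples) -> tuple[np.ndarray, np.ndarray]:
    sub = table.take_samples(samples)
    ok = sub.dosage != MISSING
    n = ok.sum(axis=0)
    k = np.where(ok, sub.dosage, 0).sum(axis=0)
    return k.astype(np.int64), n.astype(np.int64)


def estimate_omega(
    table: GenotypeTable,
    popmap: PopulationMap,
    object_pop: str,
    ref_pop: str,
    min_sites: int = 500,
) -> DriftVariance:
    """Method-of-moments drift variance.

    omega = mean over informative sites (reference frequency strictly inside
    (0,1)) of [(p_O - p_R)^2 - p_R(1-p_R)(1/(2n_O) + 1/(2n_R))] /
    [p_R(1-p_R)], floored at 1e-6.  The sampling-noise correction makes the
    estimate invariant to sample size.
    """
    kO, nO = _pop_freq_counts(table, popmap.samples_for(object_pop))
    kR, nR = _pop_freq_counts(table, popmap.samples_for(ref_pop))
    ok = (nO > 0) & (nR > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pO = np.where(ok, kO / (2.0 * nO), np.nan)
        pR = np.where(ok, kR / (2.0 * nR), np.nan)
    informative = ok & (pR > 0) & (pR < 1)
    m = int(informative.sum())
    if m < min_sites:
        raise ValueError(
            f"only {m} informative sites (<{min_sites}); omega unstable"
        )
    pO, pR = pO[informative], pR[informative]
    nO, nR = nO[informative], nR[informative]
    v = pR * (1.0 - pR)
    num = (pO - pR) ** 2 - v * (1.0 / (2 * nO) + 1.0 / (2 * nR))
    omega = float(np.mean(num / v))
    return DriftVariance(max(omega, 1e-6), n_sites=m)


def snp_weights(window_dosage: np.ndarray, p0: float = 0.95) -> np.ndarray:
    """Down-weighting of correlated SNPs in a window.

    SNPs (columns) are clustered by single linkage on pairwise r^2 > p0;
    each SNP's weight is 1/(size of its cluster), so a block of perfectly
    correlated SNPs contributes like a single SNP.
    """
    k = window_dosage.shape[1]
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for j in range(k - 1):
        r2 = _r2_one_vs_many(window_dosage[:, j], window_dosage[:, j + 1 :])
        for off in np.flatnonzero(r2 > p0):
            a, b = find(j), find(j + 1 + off)
            if a != b:
                parent[b] = a
    roots = np.array([find(i) for i in range(k)])
    _, inverse, counts = np.unique(roots, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def _cluster_weights_chromosome(
    dosage: np.ndarray, p0: float, span: int
) -> np.ndarray:
    """Chromosome-wide 1/(cluster size) weights, testing r^2 > p0 links only
    between SNPs within ``span`` neighbours (high-LD clusters are local)."""
    k = dosage.shape[1]
    parent = np.arange(k)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for j in range(k - 1):
        hi = min(k, j + 1 + span)
        r2 = _r2_one_vs_many(dosage[:, j], dosage[:, j + 1 : hi])
        for off in np.flatnonzero(r2 > p0):
            a, b = find(j), find(j + 1 + off)
            if a != b:
                parent[b] = a
    roots = np.array([find(i) for i in range(k)])
    _, inverse, counts = np.unique(roots, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def _neutral_likelihood_vector(
    k: np.ndarray, n: np.ndarray, p_ref: np.ndarray, omega: float, n_points: int = 512
) -> np.ndarray:
    """Neutral-model likelihood for many sites at once (trapezoid on (0,1)
    plus boundary point masses)."""
    sigma = np.sqrt(omega * p_ref * (1.0 - p_ref))
    mass0 = ndtr((0.0 - p_ref) / sigma)
    mass1 = 1.0 - ndtr((1.0 - p_ref) / sigma)
    L = mass0 * (k == 0) + mass1 * (k == 2 * n)
    logC = gammaln(2 * n + 1) - gammaln(k + 1) - gammaln(2 * n - k + 1)
    out = np.empty_like(L)
    for i in range(len(k)):
        # composite Gauss-Legendre with panel breaks at the integrand's
        # sharp features (the drift density's +-8 sigma band and the
        # binomial likelihood's +-8 s.d. band around k/2n), so a fixed node
        # budget resolves small drift variances and near-fixed counts alike
        ph = k[i] / (2.0 * n[i])
        sb = np.sqrt(max(ph * (1 - ph), 1.0 / (2 * n[i])) / (2 * n[i]))
        breaks = np.unique(
            np.clip(
                [0.0, p_ref[i] - 8 * sigma[i], p_ref[i] + 8 * sigma[i],
                 ph - 8 * sb, ph + 8 * sb, 1.0],
                0.0, 1.0,
            )
        )
        deg = max(4, n_points // (len(breaks) - 1))
        nodes, wts = _leggauss_cached(deg)
        total = 0.0
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            if hi <= lo:
                continue
            half = (hi - lo) / 2.0
            x = lo + half * (nodes + 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                logpmf = (
                    logC[i]
                    + np.where(k[i] == 0, 0.0, k[i] * np.log(x))
                    + np.where(2 * n[i] - k[i] == 0, 0.0,
                               (2 * n[i] - k[i]) * np.log1p(-x))
                )
            pmf = np.exp(logpmf)
            pmf[np.isnan(pmf)] = 0.0
            z = (x - p_ref[i]) / sigma[i]
            dens = np.exp(-0.5 * z * z) / (sigma[i] * np.sqrt(2 * np.pi))
            total += half * float(np.dot(wts, pmf * dens))
        out[i] = total
    return L + out


def site_loglik(
    k_obj: int,
    n_obj: int,
    p_ref: float,
    omega: float,
    model: str = "neutral",
    s: float | None = None,
    r_dist: float | None = None,
    effective_n: float = 10_000.0,
    n_points: int = 512,
) -> float:
    """Log-likelihood of observing ``k_obj`` alternate alleles among
    ``2*n_obj`` in the object population, given reference frequency
    ``p_ref`` and drift variance ``omega``.

    ``model`` is "neutral" or "sweep"; the sweep model needs ``s`` and the
    map distance ``r_dist`` (Morgans) to the putative sweep target.
    """
    if not (0.0 < p_ref < 1.0):
        raise ValueError("p_ref must be strictly inside (0, 1)")
    if k_obj > 2 * n_obj:
        raise ValueError("k_obj exceeds allele count")
    k = np.array([k_obj], dtype=np.int64)
    n = np.array([n_obj], dtype=np.int64)
    p = np.array([p_ref], dtype=float)
    L_neut = _neutral_likelihood_vector(k, n, p, omega, n_points=n_points)[0]
    if model == "neutral":
        L = L_neut
    elif model == "sweep":
        if s is None or r_dist is None:
            raise ValueError("sweep model needs s and r_dist")
        if r_dist < 0:
            raise ValueError("r_dist must be >= 0")
        c = float(escape_probability(r_dist, s, effective_n))
        B = p_ref * (k_obj == 2 * n_obj) + (1.0 - p_ref) * (k_obj == 0)
        L = c * L_neut + (1.0 - c) * B
    else:
        raise ValueError(f"unknown model {model!r}")
    if not np.isfinite(L):
        raise FloatingPointError("non-finite likelihood")
    return float(np.log(max(L, _LOG_TINY)))


def xpclr_scan(
    table: GenotypeTable,
    popmap: PopulationMap,
    object_pop: str,
    ref_pop: str,
    config: XpclrConfig | None = None,
    omega: DriftVariance | None = None,
) -> WindowTrack:
    """XP-CLR scores on a grid of points every ``config.grid_bp`` bp.

    Each grid point's window holds the SNPs within +-(window_morgans/2) of
    it on the (uniform) genetic map, truncated to the ``max_snps`` nearest;
    the score is 2 * max over the s-grid of the weighted log-likelihood-
    ratio sum, floored at 0.  Grid points with no SNPs are NaN.
    """
    cfg = config or XpclrConfig()
    table = table.snps_only()
    if omega is None:
        omega = estimate_omega(table, popmap, object_pop, ref_pop)
    kO, nO = _pop_freq_counts(table, popmap.samples_for(object_pop))
    kR, nR = _pop_freq_counts(table, popmap.samples_for(ref_pop))
    with np.errstate(invalid="ignore", divide="ignore"):
        pR = np.where(nR > 0, kR / (2.0 * nR), np.nan)
    informative = (nO > 0) & (nR > 0) & (pR > 0) & (pR < 1)

    ref_samples = popmap.samples_for(ref_pop)
    ref_dosage = table.take_samples(ref_samples).dosage
    m_per_bp = cfg.morgans_per_bp()
    half_w = cfg.window_morgans / 2.0
    s_grid = np.asarray(cfg.s_grid)
    lengths = chromosome_lengths(table)

    chroms_out, pos_out, score_out, nsnp_out = [], [], [], []
    for c, clen in lengths.items():
        idx = np.flatnonzero((table.chrom == c) & informative)
        grid = np.arange(cfg.grid_bp, clen + 1, cfg.grid_bp, dtype=np.int64)
        if len(idx) == 0:
            chroms_out.append(np.full(len(grid), c, dtype=object))
            pos_out.append(grid)
            score_out.append(np.full(len(grid), np.nan))
            nsnp_out.append(np.zeros(len(grid), dtype=np.int64))
            continue
        gpos = table.pos[idx] * m_per_bp
        L = _neutral_likelihood_vector(kO[idx], nO[idx], pR[idx], omega.omega)
        logL = np.log(np.maximum(L, _LOG_TINY))
        B = pR[idx] * (kO[idx] == 2 * nO[idx]) + (1.0 - pR[idx]) * (kO[idx] == 0)
        w = _cluster_weights_chromosome(
            ref_dosage[:, idx], cfg.p0, cfg.cluster_span_snps
        )
        ggrid = grid * m_per_bp
        lo = np.searchsorted(gpos, ggrid - half_w, side="left")
        hi = np.searchsorted(gpos, ggrid + half_w, side="right")
        scores = np.full(len(grid), np.nan)
        nsnps = np.zeros(len(grid), dtype=np.int64)
        for gi in range(len(grid)):
            sl = slice(lo[gi], hi[gi])
            if hi[gi] <= lo[gi]:
                continue
            r = np.abs(gpos[sl] - ggrid[gi])
            Lw, Bw, logLw, ww = L[sl], B[sl], logL[sl], w[sl]
            if len(r) > cfg.max_snps:
                near = np.argpartition(r, cfg.max_snps)[: cfg.max_snps]
                r, Lw, Bw, logLw, ww = r[near], Lw[near], Bw[near], logLw[near], ww[near]
            nsnps[gi] = len(r)
            best = 0.0
            for s in s_grid:
                cc = escape_probability(r, s, cfg.effective_n)
                ll = np.log(np.maximum(cc * Lw + (1.0 - cc) * Bw, _LOG_TINY))
                tot = float(np.dot(ww, ll - logLw))
                if tot > best:
                    best = tot
            scores[gi] = max(2.0 * best, 0.0)
        chroms_out.append(np.full(len(grid), c, dtype=object))
        pos_out.append(grid)
        score_out.append(scores)
        nsnp_out.append(nsnps)

    pos_all = np.concatenate(pos_out)
    return WindowTrack(
        chrom=np.concatenate(chroms_out),
        start=pos_all,
        end=pos_all.copy(),
        n_sites=np.concatenate(nsnp_out),
        value=np.concatenate(score_out),
        name=f"xpclr:{object_pop}~{ref_pop}",
    )


def rebin_max(
    track: WindowTrack,
    chrom_lengths: dict[str, int],
    window: int = 10_000,
    step: int = 1_000,
) -> WindowTrack:
    """Rebin a grid-point track onto sliding windows by max-score-in-window
    (for plotting XP-CLR alongside windowed F_ST)."""
    chroms_out, starts_out, ends_out, ns_out, vals_out, part_out = [], [], [], [], [], []
    for c, clen in chrom_lengths.items():
        in_c = track.chrom == c
        pos = track.start[in_c]
        val = track.value[in_c]
        order = np.argsort(pos)
        pos, val = pos[order], val[order]
        starts, ends, partial = window_grid(clen, window, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        vals = np.full(len(starts), np.nan)
        ns = np.zeros(len(starts), dtype=np.int64)
        for i in range(len(starts)):
            seg = val[lo[i] : hi[i]]
            seg = seg[np.isfinite(seg)]
            ns[i] = len(seg)
            if len(seg):
                vals[i] = seg.max()
        chroms_out.append(np.full(len(starts), c, dtype=object))
        starts_out.append(starts)
        ends_out.append(ends)
        ns_out.append(ns)
        vals_out.append(vals)
        part_out.append(partial)
    return WindowTrack(
        chrom=np.concatenate(chroms_out),
        start=np.concatenate(starts_out),
        end=np.concatenate(ends_out),
        n_sites=np.concatenate(ns_out),
        value=np.concatenate(vals_out),
        partial=np.concatenate(part_out),
        name=track.name + ":rebinned",
    )
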