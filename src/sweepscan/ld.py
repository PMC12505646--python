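"""Linkage disequilibrium: genotype r^2, decay curves, pruning.

r^2 here is the composite genotype measure: the squared Pearson correlation
of diploid dosage vectors over pairwise-complete samples.  It needs no
phasing, is symmetric, and is invariant to allele relabeling
(dosage -> 2 - dosage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeTable, PopulationMap


@dataclass
class DecayCurve:
    """Binned mean r^2 against pairwise physical distance.

    Bins are contiguous ``bin_width``-bp intervals from 0; ``max_r2`` is the
    maximum binned mean, and ``half_max_interval`` is the first bin beyond
    the maximum's bin whose mean drops to <= max_r2/2, reported as
    [start, end) in bp — ``None`` when the curve never drops that far.
    """

    bin_start: np.ndarray
    bin_end: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    max_r2: float
    half_max_interval: tuple[int, int] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "bin_end": self.bin_end,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def pair_r2(dosages_site1, dosages_site2) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN with <2 shared samples or zero variance."""
    x = np.asarray(dosages_site1, dtype=float)
    y = np.asarray(dosages_site2, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return float("nan")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _r2_one_vs_many(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """r^2 of column ``y`` (n,) against each column of ``X`` (n, k) with
    pairwise-complete missing handling; NaN where undefined."""
    my = y != MISSING
    MX = X != MISSING
    shared = MX & my[:, None]
    n = shared.sum(axis=0).astype(float)
    yv = np.where(my, y, 0.0)
    Xv = np.where(MX, X, 0.0)
    sy = yv @ shared
    sx = (Xv * shared).sum(axis=0)
    sxy = (Xv * (yv[:, None] * shared)).sum(axis=0)
    syy = (yv**2) @ shared
    sxx = (Xv**2 * shared).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx**2) * (n * syy - sy**2)
        r2 = np.where((n >= 2) & (den > 0), num**2 / den, np.nan)
    return r2


def decay_curve(
    table: GenotypeTable,
    popmap: PopulationMap | None = None,
    lineage: str | None = None,
    max_dist: int = 500_000,
    bin_width: int = 100,
    max_pairs_per_bin: int | None = None,
    seed: int | None = None,
) -> DecayCurve:
    """LD decay from all intra-chromosomal SNP pairs within ``max_dist`` bp.

    Pair r^2 values are binned by distance into ``bin_width``-bp bins.  With
    ``max_pairs_per_bin`` set, each bin's pairs are subsampled (seeded) —
    off by default.
    """
    if popmap is not None and lineage is not None:
        table = table.take_samples(popmap.samples_for(lineage))
    if table.n_samples < 2:
        raise ValueError("need >=2 samples for LD")
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    rng = np.random.default_rng(seed)
    reservoir: list[list] | None = None
    if max_pairs_per_bin is not None:
        reservoir = [[] for _ in range(n_bins)]
        seen = np.zeros(n_bins, dtype=np.int64)
    any_pair = False
    for c in pd.unique(pd.Series(table.chrom)):
        idx = np.flatnonzero(table.chrom == c)
        pos = table.pos[idx]
        D = table.dosage[:, idx]
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for j in range(len(idx) - 1):
            k = hi[j]
            if k <= j + 1:
                continue
            any_pair = True
            r2 = _r2_one_vs_many(D[:, j], D[:, j + 1 : k])
            dist = pos[j + 1 : k] - pos[j]
            b = np.minimum((dist // bin_width).astype(int), n_bins - 1)
            finite = np.isfinite(r2)
            if reservoir is None:
                np.add.at(sums, b[finite], r2[finite])
                np.add.at(counts, b[finite], 1)
            else:
                for bb, rr in zip(b[finite], r2[finite]):
                    seen[bb] += 1
                    if len(reservoir[bb]) < max_pairs_per_bin:
                        reservoir[bb].append(rr)
                    else:  # reservoir sampling keeps a uniform subsample
                        t = rng.integers(0, seen[bb])
                        if t < max_pairs_per_bin:
                            reservoir[bb][t] = rr
    if not any_pair:
        raise ValueError("no SNP pairs within max_dist")
    if reservoir is not None:
        sums = np.array([np.sum(r) for r in reservoir])
        counts = np.array([len(r) for r in reservoir], dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    bin_start = np.arange(n_bins, dtype=np.int64) * bin_width
    bin_end = bin_start + bin_width
    defined = np.flatnonzero(counts > 0)
    i_max = defined[np.nanargmax(mean_r2[defined])]
    max_r2 = float(mean_r2[i_max])
    half = None
    for i in range(i_max + 1, n_bins):
        if counts[i] > 0 and mean_r2[i] <= max_r2 / 2.0:
            half = (int(bin_start[i]), int(bin_end[i]))
            break
    return DecayCurve(bin_start, bin_end, mean_r2, counts, max_r2, half)


def ld_prune(
    table: GenotypeTable,
    window: int = 10_000,
    step_snps: int = 1,
    r2_threshold: float = 0.5,
) -> GenotypeTable:
    """Greedy left-to-right LD pruning.

    Scanning each chromosome in position order, a SNP is dropped when its
    r^2 with any retained SNP no more than ``window`` bp behind it exceeds
    ``r2_threshold``; the scan advances ``step_snps`` at a time (1 = every
    SNP considered).  The output contains no retained pair within ``window``
    bp with r^2 above the threshold.
    """
    keep_global: list[int] = []
    for c in pd.unique(pd.Series(table.chrom)):
        idx = np.flatnonzero(table.chrom == c)
        pos = table.pos[idx]
        D = table.dosage[:, idx]
        kept: list[int] = []  # local indices
        for j in range(0, len(idx), step_snps):
            lo = pos[j] - window
            back = [k for k in kept if pos[k] >= lo]
            if back:
                r2 = _r2_one_vs_many(D[:, j], D[:, back])
                if np.any(r2 > r2_threshold):
                    continue
            kept.append(j)
        keep_global.extend(idx[kept])
    return table.take_sites(np.sort(keep_global))
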