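"""Weir-Cockerham (1984) F_ST for pairs of populations.

The estimator decomposes allele-frequency variance at each biallelic site
into among-population (a), among-individuals-within-population (b) and
within-individual (c) components.  The per-site ratio is a/(a+b+c);
"mean" F_ST averages per-site ratios, "weighted" F_ST is sum(a)/sum(a+b+c)
over all usable sites.  Negative per-site ratios are retained (not
clamped), matching common tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import WindowTrack, _windowed_sum
from .io import MISSING, GenotypeTable, PopulationMap


@dataclass
class FstComponents:
    """Per-site WC84 variance components (r=2 populations)."""

    a: float
    b: float
    c: float

    @property
    def ratio(self) -> float:
        tot = self.a + self.b + self.c
        return self.a / tot if tot != 0 else float("nan")


def _pop_stats(dosage: np.ndarray):
    """Per-site (n, p, h) for one population's dosage block: non-missing
    diploid count, alt frequency, observed heterozygote proportion."""
    ok = dosage != MISSING
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, dosage, 0).sum(axis=0) / (2.0 * n)
        h = (dosage == 1).sum(axis=0) / n
    return n, p, h


def fst_components_vector(dos1: np.ndarray, dos2: np.ndarray):
    """Vectorised WC84 components over all sites.

    Returns (a, b, c, usable): arrays per site; ``usable`` is False where a
    population has no data, the mean sample size is <= 1, or the site is
    monomorphic across both populations.
    """
    n1, p1, h1 = _pop_stats(np.atleast_2d(dos1))
    n2, p2, h2 = _pop_stats(np.atleast_2d(dos2))
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
    c = hbar / 2.0
    usable = (n1 > 0) & (n2 > 0) & (nbar > 1) & (pbar > 0) & (pbar < 1) & (nc > 0)
    return a, b, c, usable


def site_fst_components(dosages_pop1, dosages_pop2) -> FstComponents:
    """WC84 components at a single site (raises on a site monomorphic across
    both populations or without data in either)."""
    d1 = np.asarray(dosages_pop1).reshape(-1, 1)
    d2 = np.asarray(dosages_pop2).reshape(-1, 1)
    a, b, c, usable = fst_components_vector(d1, d2)
    if not usable[0]:
        raise ValueError("site unusable: monomorphic or missing a population")
    return FstComponents(float(a[0]), float(b[0]), float(c[0]))


def _site_ratios(table: GenotypeTable, popmap: PopulationMap, popA: str, popB: str):
    subA = table.take_samples(popmap.samples_for(popA))
    subB = table.take_samples(popmap.samples_for(popB))
    a, b, c, usable = fst_components_vector(subA.dosage, subB.dosage)
    tot = a + b + c
    usable = usable & (tot != 0) & np.isfinite(tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(usable, a / tot, np.nan)
    return a, tot, ratio, usable


def windowed_fst(
    table: GenotypeTable,
    popmap: PopulationMap,
    popA: str,
    popB: str,
    window: int = 10_000,
    step: int = 1_000,
) -> WindowTrack:
    """Sliding-window mean of per-site WC84 ratios (NaN where a window has no
    usable site)."""
    _, _, ratio, usable = _site_ratios(table, popmap, popA, popB)
    return _windowed_sum(
        table, ratio, usable, window, step, name=f"fst:{popA}~{popB}", mean=True
    )


def global_fst(
    table: GenotypeTable, popmap: PopulationMap, popA: str, popB: str
) -> tuple[float, float]:
    """(mean_fst, weighted_fst) across all usable sites."""
    a, tot, ratio, usable = _site_ratios(table, popmap, popA, popB)
    if not usable.any():
        raise ValueError(f"no usable sites for {popA} vs {popB}")
    mean_fst = float(np.nanmean(ratio[usable]))
    weighted = float(a[usable].sum() / tot[usable].sum())
    return mean_fst, weighted
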