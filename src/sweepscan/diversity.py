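"""Nucleotide diversity, per-sample heterozygosity/inbreeding, p-distance.

Windowed pi follows the VCFtools ``--window-pi`` convention: per-site
unbiased heterozygosity summed over the variant sites of a window and
divided by the window length in bp, so monomorphic positions contribute
zero.  Windows default to 10 kb with a 1 kb step (overlapping); a
non-overlapping scan is ``step == window``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeTable, PopulationMap


@dataclass
class WindowTrack:
    """Per-genomic-window score series (pi, F_ST or XP-CLR).

    ``value`` is NaN where the window statistic is undefined.  ``partial``
    marks terminal windows shorter than the configured size.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    n_sites: np.ndarray
    value: np.ndarray
    partial: np.ndarray | None = None
    name: str = ""

    def __len__(self) -> int:
        return len(self.start)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.value)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "n_sites": self.n_sites,
                "value": self.value,
            }
        )
        if self.partial is not None:
            df["partial"] = self.partial
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "") -> "WindowTrack":
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
            n_sites=df["n_sites"].to_numpy(dtype=np.int64),
            value=df["value"].to_numpy(dtype=float),
            partial=df["partial"].to_numpy(dtype=bool) if "partial" in df else None,
            name=name,
        )


@dataclass
class SampleHetSummary:
    """Observed heterozygosity and method-of-moments inbreeding F for one
    sample (``het_pct``/``inbreeding_f`` are NaN when no site is usable)."""

    sample_id: str
    n_sites: int
    het_pct: float
    inbreeding_f: float


def chromosome_lengths(table: GenotypeTable) -> dict[str, int]:
    """Contig lengths from the header when present, else the last variant
    position per chromosome."""
    out = {}
    for c in pd.unique(pd.Series(table.chrom)):
        if c in table.contig_lengths:
            out[c] = int(table.contig_lengths[c])
        else:
            out[c] = int(table.pos[table.chrom == c].max())
    return out


def window_grid(chrom_len: int, window: int, step: int):
    """(start, end, partial) triples covering [1, chrom_len]."""
    starts = np.arange(1, chrom_len + 1, step, dtype=np.int64)
    ends = np.minimum(starts + window - 1, chrom_len)
    return starts, ends, (ends - starts + 1) < window


def site_pi(dosages_at_site: np.ndarray) -> float:
    """Unbiased per-site diversity 2*c0*c1 / (n*(n-1)) over the n non-missing
    alleles; NaN when fewer than two alleles are observed."""
    d = np.asarray(dosages_at_site)
    d = d[d != MISSING]
    n = 2 * len(d)
    if n < 2:
        return float("nan")
    c1 = int(d.sum())
    c0 = n - c1
    return 2.0 * c0 * c1 / (n * (n - 1))


def _site_pi_vector(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised site_pi over all columns; second array flags usable sites."""
    ok = dosage != MISSING
    n = 2 * ok.sum(axis=0)
    c1 = np.where(ok, dosage, 0).sum(axis=0)
    c0 = n - c1
    usable = n >= 2
    pi = np.zeros(dosage.shape[1])
    nn = n[usable]
    pi[usable] = 2.0 * c0[usable] * c1[usable] / (nn * (nn - 1.0))
    return pi, usable


def windowed_pi(
    table: GenotypeTable,
    popmap: PopulationMap,
    lineage: str,
    window: int = 10_000,
    step: int = 1_000,
) -> WindowTrack:
    """Sliding-window nucleotide diversity for one lineage.

    Allele counts use only the lineage's samples (per-subpopulation pi).
    Empty windows have value 0 with ``n_sites`` 0; terminal partial windows
    are divided by their actual length and flagged.
    """
    samples = popmap.samples_for(lineage)
    if len(samples) < 2:
        raise ValueError(f"lineage {lineage!r} has <2 samples")
    sub = table.take_samples(samples)
    pi, usable = _site_pi_vector(sub.dosage)
    return _windowed_sum(table, pi, usable, window, step, name=f"pi:{lineage}")


def _windowed_sum(table, per_site, usable, window, step, name,
                  mean: bool = False) -> WindowTrack:
    """Aggregate a per-site series onto the window grid (sum/len or mean)."""
    chroms_out, starts_out, ends_out, ns_out, vals_out, part_out = [], [], [], [], [], []
    lengths = chromosome_lengths(table)
    contrib = np.where(usable, per_site, 0.0)
    for c, clen in lengths.items():
        idx = np.flatnonzero(table.chrom == c)
        pos_c = table.pos[idx]
        cum = np.concatenate([[0.0], np.cumsum(contrib[idx])])
        cum_n = np.concatenate([[0], np.cumsum(usable[idx].astype(np.int64))])
        starts, ends, partial = window_grid(clen, window, step)
        lo = np.searchsorted(pos_c, starts, side="left")
        hi = np.searchsorted(pos_c, ends, side="right")
        s = cum[hi] - cum[lo]
        n = cum_n[hi] - cum_n[lo]
        if mean:
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(n > 0, s / n, np.nan)
        else:
            v = s / (ends - starts + 1)
        chroms_out.append(np.full(len(starts), c, dtype=object))
        starts_out.append(starts)
        ends_out.append(ends)
        ns_out.append(n)
        vals_out.append(v)
        part_out.append(partial)
    return WindowTrack(
        chrom=np.concatenate(chroms_out),
        start=np.concatenate(starts_out),
        end=np.concatenate(ends_out),
        n_sites=np.concatenate(ns_out),
        value=np.concatenate(vals_out),
        partial=np.concatenate(part_out),
        name=name,
    )


def sample_heterozygosity(table: GenotypeTable) -> list[SampleHetSummary]:
    """Observed het%% and inbreeding F per sample.

    F = (O_hom - E_hom) / (N - E_hom) with the expected homozygosity per site
    E_hom = 1 - 2p(1-p) * 2n/(2n-1) (p = panel-wide alt frequency, n =
    panel-wide non-missing diploid count), summed over the sites non-missing
    in the sample — the per-site form of the VCFtools ``--het`` estimator.
    """
    if table.n_samples < 1:
        raise ValueError("need at least one sample")
    ok = table.dosage != MISSING
    n_site = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, table.dosage, 0).sum(axis=0) / (2.0 * n_site)
    valid = n_site >= 1
    e_hom = np.zeros(table.n_sites)
    nn = n_site[valid].astype(float)
    e_hom[valid] = 1.0 - 2.0 * p[valid] * (1.0 - p[valid]) * (2 * nn) / (2 * nn - 1.0)
    use = ok & valid  # per sample x site
    N = use.sum(axis=1)
    o_hom = (use & (table.dosage != 1)).sum(axis=1)
    e = use @ e_hom
    out = []
    for i, sid in enumerate(table.sample_ids):
        if N[i] == 0:
            out.append(SampleHetSummary(sid, 0, float("nan"), float("nan")))
            continue
        het = 100.0 * (N[i] - o_hom[i]) / N[i]
        denom = N[i] - e[i]
        f = (o_hom[i] - e[i]) / denom if denom != 0 else float("nan")
        out.append(SampleHetSummary(sid, int(N[i]), float(het), float(f)))
    return out


def p_distance_matrix(
    table: GenotypeTable, min_shared: int = 100, allow_undefined: bool = False
) -> np.ndarray:
    """Pairwise p-distance: mean |dosage_i - dosage_j| / 2 over the sites
    non-missing in both samples.

    Symmetric with a zero diagonal.  A pair with zero shared sites raises
    unless ``allow_undefined`` (then NaN).  Pairs sharing fewer than
    ``min_shared`` sites trigger a reliability warning.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    d = table.dosage
    ok = (d != MISSING).astype(np.float64)
    x0 = ((d == 0) & (ok > 0)).astype(np.float64)
    x1 = (d == 1).astype(np.float64)
    x2 = (d == 2).astype(np.float64)
    shared = ok @ ok.T
    # |di - dj| summed over shared sites, via one-hot cross products
    diff1 = x0 @ x1.T + x1 @ x0.T + x1 @ x2.T + x2 @ x1.T
    diff2 = 2.0 * (x0 @ x2.T + x2 @ x0.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (diff1 + diff2) / (2.0 * shared)
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices_from(shared, k=1)
    if np.any(shared[iu] == 0):
        if not allow_undefined:
            raise ValueError("sample pair with zero shared non-missing sites")
    elif np.any(shared[iu] < min_shared):
        import warnings

        warnings.warn(
            f"p-distance pairs with < {min_shared} shared sites are unreliable",
            stacklevel=2,
        )
    return dist
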