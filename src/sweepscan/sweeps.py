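"""Composite sweep calling: percentile thresholds on two genome scans,
interval overlap and merging, per-chromosome summaries, gene intersection,
lineage set comparisons, and the pi-contrast candidate screen.

The caller mirrors the standard two-scan recipe: take the empirical top 5%
of XP-CLR grid windows and of windowed F_ST, intersect the two region sets,
and merge the result; genes overlapping the merged regions by >= 1 bp are
the candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import WindowTrack
from .io import GeneCatalog

Interval = tuple[str, int, int]


def _merge_intervals(intervals: list[Interval], max_gap: int = 0) -> list[Interval]:
    """Union of 1-based inclusive intervals; intervals separated by a gap of
    at most ``max_gap`` bp are joined (gap 0 merges book-ended intervals)."""
    if not intervals:
        return []
    out: list[Interval] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start - out[-1][2] - 1 <= max_gap:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


@dataclass
class RegionSet:
    """Sorted, non-overlapping 1-based inclusive genomic intervals."""

    intervals: list[Interval]
    label: str = ""

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start > end:
                raise ValueError(f"interval start > end: {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def merged(self, max_gap: int = 0) -> "RegionSet":
        return RegionSet(_merge_intervals(self.intervals, max_gap), self.label)


@dataclass
class SweepSummary:
    """Per-chromosome sweep-region statistics plus grand total/average rows
    (the total-length / maximum-length / average-length / count layout)."""

    per_chrom: pd.DataFrame  # chrom, total_bp, max_bp, avg_bp, n_sweeps
    grand_total: dict = field(default_factory=dict)
    grand_average: dict = field(default_factory=dict)


def nearest_rank_threshold(values: np.ndarray, q: float) -> float:
    """The ceil(q*n)-th order statistic (1-based) of the finite values."""
    v = np.sort(np.asarray(values)[np.isfinite(values)])
    if len(v) == 0:
        raise ValueError("no defined values")
    rank = max(1, math.ceil(q * len(v)))
    return float(v[rank - 1])


def top_percentile_regions(track: WindowTrack, q: float = 0.95) -> RegionSet:
    """Windows at or above the genome-wide empirical q-th percentile,
    unioned into intervals.

    The threshold is nearest-rank over defined windows; selection is
    inclusive (>= threshold) so ties keep the nominal top slice non-empty.
    Requires >= 20 defined windows; raises when every value is identical
    (degenerate percentile).
    """
    defined = track.defined()
    vals = track.value[defined]
    if len(vals) < 20:
        raise ValueError(f"only {len(vals)} defined windows (<20)")
    if np.all(vals == vals[0]):
        raise ValueError("all window values identical; percentile degenerate")
    thr = nearest_rank_threshold(vals, q)
    sel = defined & (track.value >= thr)
    intervals = [
        (track.chrom[i], int(track.start[i]), int(track.end[i]))
        for i in np.flatnonzero(sel)
    ]
    return RegionSet(_merge_intervals(intervals), label=f"{track.name}:top{q:g}")


def overlap_regions(set_a: RegionSet, set_b: RegionSet) -> RegionSet:
    """Base-pair intersection of two merged region sets."""
    a = set_a.merged().intervals
    b = set_b.merged().intervals
    out: list[Interval] = []
    by_chrom_b: dict[str, list[Interval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv[0], []).append(iv)
    for chrom, s1, e1 in a:
        for _, s2, e2 in by_chrom_b.get(chrom, []):
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                out.append((chrom, lo, hi))
    return RegionSet(_merge_intervals(out), label=f"{set_a.label}&{set_b.label}")


def merge_regions(regions: RegionSet, max_gap: int = 0) -> RegionSet:
    """bedtools-merge semantics: overlapping or book-ended intervals joined;
    ``max_gap`` extends merging across gaps of at most that many bp."""
    return regions.merged(max_gap)


def call_sweeps(
    scan_a: WindowTrack, scan_b: WindowTrack, q: float = 0.95
) -> RegionSet:
    """The composite caller: overlap of the two scans' top-(1-q) regions,
    merged."""
    return merge_regions(
        overlap_regions(top_percentile_regions(scan_a, q), top_percentile_regions(scan_b, q))
    )


def summarize_sweeps(regions: RegionSet) -> SweepSummary:
    """Per-chromosome total/maximum/average length (bp, average rounded to
    integer) and sweep count, with grand rows: 'total' sums, 'average' the
    per-chromosome column means."""
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, s, e in regions.intervals:
        by_chrom.setdefault(chrom, []).append(e - s + 1)
    for chrom in sorted(by_chrom):
        lens = by_chrom[chrom]
        rows.append(
            {
                "chrom": chrom,
                "total_bp": int(sum(lens)),
                "max_bp": int(max(lens)),
                "avg_bp": int(round(sum(lens) / len(lens))),
                "n_sweeps": len(lens),
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "total_bp", "max_bp", "avg_bp", "n_sweeps"])
    if len(df):
        grand_total = {
            "total_bp": int(df["total_bp"].sum()),
            "n_sweeps": int(df["n_sweeps"].sum()),
        }
        grand_average = {
            "total_bp": int(round(df["total_bp"].mean())),
            "avg_bp": int(round(df["avg_bp"].mean())),
            "n_sweeps": int(round(df["n_sweeps"].mean())),
        }
    else:
        grand_total = {"total_bp": 0, "n_sweeps": 0}
        grand_average = {"total_bp": 0, "avg_bp": 0, "n_sweeps": 0}
    return SweepSummary(df, grand_total, grand_average)


def genes_in_regions(regions: RegionSet, catalog: GeneCatalog) -> list[str]:
    """Unique, sorted ids of genes overlapping any region by >= 1 bp."""
    hits: set[str] = set()
    merged = regions.merged().intervals
    by_chrom: dict[str, list[Interval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv[0], []).append(iv)
    for gid, chrom, gs, ge in zip(
        catalog.gene_id, catalog.chrom, catalog.start, catalog.end
    ):
        for _, rs, re_ in by_chrom.get(chrom, []):
            if gs <= re_ and ge >= rs:
                hits.add(str(gid))
                break
    return sorted(hits)


def lineage_gene_venn(gene_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exact exclusive counts for every non-empty intersection class of the
    given gene sets, keyed by the sorted tuple of member labels."""
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 gene sets")
    labels = sorted(gene_sets)
    universe = set().union(*gene_sets.values())
    out: dict[tuple[str, ...], int] = {}
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set(universe)
            for l in combo:
                inside &= gene_sets[l]
            for l in labels:
                if l not in combo:
                    inside -= gene_sets[l]
            out[combo] = len(inside)
    return out


def _check_same_grid(tracks: dict[str, WindowTrack]) -> None:
    items = list(tracks.values())
    first = items[0]
    for t in items[1:]:
        if (
            len(t) != len(first)
            or not np.array_equal(t.start, first.start)
            or not np.array_equal(t.end, first.end)
            or not np.array_equal(t.chrom, first.chrom)
        ):
            raise ValueError("pi tracks do not share a window grid")


def pi_contrast_screen(
    pi_tracks: dict[str, WindowTrack],
    cultivated: list[str],
    wild: str,
    low_q: float = 0.05,
    high_q: float = 0.50,
) -> RegionSet:
    """Windows with exceptionally low diversity in every cultivated lineage
    but at least median diversity in the wild lineage, unioned into regions.

    "Exceptionally low" is each cultivated track's own ``low_q`` nearest-rank
    quantile (inclusive, <=); "high" is the wild track's ``high_q`` quantile
    (inclusive, >=).  All tracks must share one window grid.
    """
    _check_same_grid(pi_tracks)
    wild_track = pi_tracks[wild]
    wd = wild_track.defined()
    wild_thr = nearest_rank_threshold(wild_track.value[wd], high_q)
    sel = wd & (wild_track.value >= wild_thr)
    for lab in cultivated:
        t = pi_tracks[lab]
        d = t.defined()
        thr = nearest_rank_threshold(t.value[d], low_q)
        sel &= d & (t.value <= thr)
    intervals = [
        (wild_track.chrom[i], int(wild_track.start[i]), int(wild_track.end[i]))
        for i in np.flatnonzero(sel)
    ]
    label = f"pi-contrast(low_q={low_q:g},high_q={high_q:g})"
    return RegionSet(_merge_intervals(intervals), label=label)


@dataclass
class GenePiProfile:
    """Per-lineage pi window series around one gene (for diversity plots)."""

    gene_id: str
    chrom: str
    gene_start: int
    gene_end: int
    tracks: dict[str, pd.DataFrame]


def gene_pi_profile(
    gene_id: str,
    pi_tracks: dict[str, WindowTrack],
    catalog: GeneCatalog,
    flank: int = 50_000,
) -> GenePiProfile:
    """Each lineage's pi windows overlapping ``gene +- flank``, annotated
    with the gene boundaries (raises on an unknown gene)."""
    hit = np.flatnonzero(catalog.gene_id == gene_id)
    if len(hit) == 0:
        raise KeyError(f"unknown gene {gene_id!r}")
    i = hit[0]
    chrom, gs, ge = str(catalog.chrom[i]), int(catalog.start[i]), int(catalog.end[i])
    lo, hi = max(1, gs - flank), ge + flank
    out: dict[str, pd.DataFrame] = {}
    for lab, t in pi_tracks.items():
        sel = (t.chrom == chrom) & (t.end >= lo) & (t.start <= hi)
        out[lab] = t.to_frame()[sel].reset_index(drop=True)
    return GenePiProfile(gene_id, chrom, gs, ge, out)
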