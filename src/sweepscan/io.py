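"""Readers, writers and variant filters.

The central container is :class:`GenotypeTable`: a samples x sites matrix of
diploid allele dosages (0 = hom ref, 1 = het, 2 = hom alt, ``MISSING`` = no
call) with per-site metadata (chromosome, 1-based position, alleles, optional
per-genotype read depth and per-site INFO annotations such as QD/FS/MQ).

Coordinates are 1-based inclusive internally (VCF convention); BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid dosage or depth.
MISSING: int = -1

#: GATK-style SNP hard-filter expression used as the default: a site is
#: removed when any criterion fires.
SNP_HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "SOR": (">", 3.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}

#: INFO keys the VCF reader collects when present.
INFO_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")


class VcfParseError(ValueError):
    """Malformed VCF content (carries the offending record number)."""


class PopmapError(KeyError):
    """Samples present in the genotype data but absent from the popmap."""


@dataclass
class GenotypeTable:
    """Biallelic diploid genotype matrix with per-site metadata.

    Attributes
    ----------
    sample_ids
        Sample identifiers, one per matrix row.
    chrom, pos
        Per-site chromosome label and 1-based position; positions are
        strictly increasing within a chromosome.
    ref, alt
        Reference and alternate allele strings.
    dosage
        ``int8`` array of shape ``(n_samples, n_sites)`` with values in
        {0, 1, 2} or :data:`MISSING`.
    depth
        Optional per-genotype read depth, same shape as ``dosage``
        (:data:`MISSING` where absent).
    info
        Optional per-site INFO annotations, each a float array with NaN
        where the annotation is missing.
    is_snp
        Per-site flag distinguishing SNPs from INDELs.
    contig_lengths
        Chromosome lengths (bp) when known, e.g. from VCF ``##contig`` lines.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray | None = None
    info: dict[str, np.ndarray] = field(default_factory=dict)
    is_snp: np.ndarray | None = None
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        """Assert the container invariants; raise ``ValueError`` on breach."""
        if self.dosage.shape != (self.n_samples, self.n_sites):
            raise ValueError("dosage shape does not match samples x sites")
        vals = np.unique(self.dosage)
        if not np.all(np.isin(vals, [MISSING, 0, 1, 2])):
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {vals}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def take_sites(self, idx) -> "GenotypeTable":
        """New table restricted to the given site indices (order preserved)."""
        idx = np.asarray(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            info={k: v[idx] for k, v in self.info.items()},
            is_snp=None if self.is_snp is None else self.is_snp[idx],
        )

    def take_samples(self, sample_ids) -> "GenotypeTable":
        """New table restricted to (and ordered by) the given sample ids."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        rows = np.array([index[s] for s in sample_ids])
        return replace(
            self,
            sample_ids=list(sample_ids),
            dosage=self.dosage[rows],
            depth=None if self.depth is None else self.depth[rows],
        )

    def snps_only(self) -> "GenotypeTable":
        """Drop INDEL sites (downstream scans operate on SNPs)."""
        if self.is_snp is None:
            return self
        return self.take_sites(np.flatnonzero(self.is_snp))

    def alt_frequency(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing genotypes
        (NaN where every genotype is missing)."""
        ok = self.dosage != MISSING
        n = ok.sum(axis=0)
        alt = np.where(ok, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)


@dataclass
class PopulationMap:
    """Mapping from sample id to lineage label."""

    assignments: dict[str, str]

    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def samples_for(self, label: str) -> list[str]:
        return [s for s, l in self.assignments.items() if l == label]

    def validate_against(self, sample_ids) -> None:
        """Every sample must carry exactly one label."""
        absent = [s for s in sample_ids if s not in self.assignments]
        if absent:
            raise PopmapError(f"samples missing from popmap: {absent}")


@dataclass
class GeneCatalog:
    """Gene intervals from GFF3 (1-based inclusive)."""

    gene_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray

    def __post_init__(self):
        if len(set(self.gene_id)) != len(self.gene_id):
            raise ValueError("duplicate gene_id in catalog")
        if np.any(self.start > self.end):
            raise ValueError("gene with start > end")

    def __len__(self) -> int:
        return len(self.gene_id)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, region: str | None = None) -> GenotypeTable:
    """Read a (possibly bgzipped) VCF into a :class:`GenotypeTable`.

    Multiallelic records are skipped with a warning; ``./.`` genotypes become
    missing dosages; non-diploid genotypes raise, naming the sample.
    ``region`` is ``"chrom"`` or ``"chrom:start-end"`` (1-based inclusive).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    contigs = {}
    try:
        contigs = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:  # header without lengths
        pass

    has_dp = "##FORMAT=<ID=DP," in vcf.raw_header
    want_chrom, want_lo, want_hi = None, None, None
    if region is not None:
        if ":" in region:
            want_chrom, span = region.split(":", 1)
            lo, hi = span.split("-")
            want_lo, want_hi = int(lo), int(hi)
        else:
            want_chrom = region

    chroms, poss, refs, alts, snps = [], [], [], [], []
    dosages, depths = [], []
    info_cols: dict[str, list] = {k: [] for k in INFO_KEYS}
    seen_info: set[str] = set()
    n_multi = 0
    for rec_no, v in enumerate(vcf, start=1):
        try:
            if want_chrom is not None and v.CHROM != want_chrom:
                continue
            if want_lo is not None and not (want_lo <= v.POS <= want_hi):
                continue
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            gts = v.genotypes
            for s_i, g in enumerate(gts):
                if len(g) != 3:  # [allele_a, allele_b, phased]
                    raise VcfParseError(
                        f"non-diploid genotype for sample {samples[s_i]} "
                        f"at record {rec_no} ({v.CHROM}:{v.POS})"
                    )
            # gts012: 0/1/2 dosage, 3 = unknown
            d = v.gt_types.astype(np.int8)
            d[d == 3] = MISSING
            dosages.append(d)
            dp = v.format("DP") if has_dp else None
            if dp is not None:
                dp = dp.reshape(-1).astype(np.int32)
                dp[dp < 0] = MISSING
                depths.append(dp)
            else:
                depths.append(np.full(len(samples), MISSING, dtype=np.int32))
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            snps.append(len(v.REF) == 1 and len(v.ALT[0]) == 1)
            for k in INFO_KEYS:
                val = v.INFO.get(k)
                if val is not None:
                    seen_info.add(k)
                info_cols[k].append(np.nan if val is None else float(val))
        except VcfParseError:
            raise
        except Exception as exc:  # pragma: no cover - htslib-level failures
            raise VcfParseError(f"malformed VCF record {rec_no}: {exc}") from exc

    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records", stacklevel=2)

    n_sites = len(poss)
    dosage = (
        np.stack(dosages, axis=1)
        if n_sites
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    depth = (
        np.stack(depths, axis=1)
        if n_sites
        else np.empty((len(samples), 0), dtype=np.int32)
    )
    if not np.any(depth != MISSING):
        depth = None
    table = GenotypeTable(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
        depth=depth,
        info={k: np.array(info_cols[k], dtype=float) for k in seen_info},
        is_snp=np.array(snps, dtype=bool),
        contig_lengths=contigs,
    )
    table.validate()
    return table


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when depths are present)."""
    has_dp = table.depth is not None
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, l in table.contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        for k in sorted(table.info):
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        fmt = "GT:DP" if has_dp else "GT"
        for j in range(table.n_sites):
            if table.info:
                parts = []
                for k in sorted(table.info):
                    v = table.info[k][j]
                    if np.isfinite(v):
                        parts.append(f"{k}={v:g}")
                info = ";".join(parts) if parts else "."
            else:
                info = "."
            cells = []
            for i in range(table.n_samples):
                g = gt_str[int(table.dosage[i, j])]
                if has_dp:
                    dp = int(table.depth[i, j])
                    g = f"{g}:{dp if dp != MISSING else '.'}"
                cells.append(g)
            fh.write(
                f"{table.chrom[j]}\t{table.pos[j]}\t.\t{table.ref[j]}\t"
                f"{table.alt[j]}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Filters


def hard_filter_mask(
    table: GenotypeTable, thresholds: dict[str, tuple[str, float]] | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Per-site keep mask under GATK-style hard filters, plus per-criterion
    removal counts.  A missing annotation passes its criterion (GATK
    behaviour for absent INFO fields)."""
    if thresholds is None:
        thresholds = SNP_HARD_FILTERS
    unknown = set(thresholds) - set(INFO_KEYS)
    if unknown:
        raise ValueError(f"unknown hard-filter keys: {sorted(unknown)}")
    fail_any = np.zeros(table.n_sites, dtype=bool)
    counts: dict[str, int] = {}
    for key, (op, cut) in thresholds.items():
        if op not in ("<", ">"):
            raise ValueError(f"hard-filter operator must be '<' or '>', got {op!r}")
        vals = table.info.get(key)
        if vals is None:
            counts[key] = 0
            continue
        with np.errstate(invalid="ignore"):
            fail = (vals < cut) if op == "<" else (vals > cut)
        fail &= np.isfinite(vals)
        counts[key] = int(fail.sum())
        fail_any |= fail
    return ~fail_any, counts


def apply_hard_filters(
    table: GenotypeTable, thresholds: dict[str, tuple[str, float]] | None = None
) -> GenotypeTable:
    """Remove sites failing any hard-filter criterion (strict inequalities:
    boundary values are retained)."""
    keep, counts = hard_filter_mask(table, thresholds)
    for key, n in counts.items():
        logger.info("hard filter %s removed %d sites", key, n)
    logger.info("hard filters removed %d of %d sites", (~keep).sum(), table.n_sites)
    return table.take_sites(np.flatnonzero(keep))


def apply_site_filters(
    table: GenotypeTable,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
    min_mean_depth: float = 5.0,
    gt_depth_range: tuple[int, int] = (2, 50),
) -> GenotypeTable:
    """Genotype-depth masking followed by site-level missingness / MAF /
    mean-depth filters.

    Genotypes with depth outside ``gt_depth_range`` (inclusive) are set to
    missing FIRST; then sites are removed when missingness exceeds
    ``max_missing``, minor-allele frequency is not strictly above ``min_maf``
    (computed from non-missing dosages), or mean depth over non-missing
    genotypes is not strictly above ``min_mean_depth``.  Depth criteria are
    skipped when the table has no depths.
    """
    dosage = table.dosage.copy()
    depth = None
    if table.depth is not None:
        depth = table.depth.copy()
        lo, hi = gt_depth_range
        bad = (depth != MISSING) & ((depth < lo) | (depth > hi))
        dosage[bad] = MISSING
        depth[bad] = MISSING
        logger.info("depth masking set %d genotypes to missing", int(bad.sum()))
    table = replace(table, dosage=dosage, depth=depth)

    ok = table.dosage != MISSING
    n_ok = ok.sum(axis=0)
    miss_frac = 1.0 - n_ok / table.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, table.dosage, 0).sum(axis=0) / (2.0 * n_ok)
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_frac <= max_missing) & (n_ok > 0) & (maf > min_maf)
    if table.depth is not None:
        dp_ok = table.depth != MISSING
        n_dp = dp_ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_dp = np.where(dp_ok, table.depth, 0).sum(axis=0) / n_dp
        keep &= (n_dp > 0) & (mean_dp > min_mean_depth)
    if not keep.any():
        warnings.warn("site filters removed every site", stacklevel=2)
    logger.info("site filters kept %d of %d sites", int(keep.sum()), table.n_sites)
    return table.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Popmap / GFF3 / BED / CSV


def read_popmap(path) -> PopulationMap:
    """Two-column delimited text: sample_id <tab> lineage."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["sample", "lineage"],
                     dtype=str, comment="#")
    return PopulationMap(dict(zip(df["sample"], df["lineage"])))


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, l in popmap.assignments.items():
            fh.write(f"{s}\t{l}\n")


def read_gff(path) -> GeneCatalog:
    """Gene features from GFF3 (``type == gene``; ID= attribute as gene_id)."""
    ids, chroms, starts, ends, strands = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            gid = None
            for kv in f[8].split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
                    break
            if gid is None:
                gid = f"{f[0]}:{f[3]}-{f[4]}"
            ids.append(gid)
            chroms.append(f[0])
            starts.append(int(f[3]))
            ends.append(int(f[4]))
            strands.append(f[6])
    return GeneCatalog(
        gene_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype=object),
    )


def write_bed(regions, path) -> None:
    """Write intervals as BED (internal 1-based inclusive -> 0-based
    half-open).  ``regions`` is a RegionSet or an iterable of
    (chrom, start, end) tuples."""
    intervals = getattr(regions, "intervals", regions)
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED back into 1-based inclusive (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


def write_track_csv(track, path) -> None:
    """CSV export of a window track (chrom,start,end,n_sites,value)."""
    track.to_frame().to_csv(path, index=False)


def read_track_csv(path):
    from .diversity import WindowTrack

    return WindowTrack.from_frame(pd.read_csv(path))
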