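"""Summary arithmetic, a positional variant classifier, and pipeline
orchestration.

Percentages are rounded half-up to one decimal and always reported with
their denominator, so a class can never silently switch its reference
total.  The variant classifier is positional: CDS > gene body (intron
proxy) > 5 kb flank (up/downstream) > intergenic; coding consequences
(synonymous / missense / nonsense) are computed only when a CDS model with
sequence is supplied.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, fst, io, ld, phylo, sweeps, xpclr
from .diversity import WindowTrack, chromosome_lengths, window_grid
from .io import GenotypeTable, GeneCatalog


def round1(x: float) -> float:
    """Half-up rounding to one decimal (the printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int) -> float:
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round1(100.0 * count / denominator)


@dataclass
class VariantClassSummary:
    """Counts, their denominators, and half-up one-decimal percentages."""

    counts: dict[str, int]
    denominators: dict[str, int]
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.percentages:
            self.percentages = {
                k: percentage(v, self.denominators[k]) for k, v in self.counts.items()
            }


def summarize_variant_classes(
    counts: dict[str, tuple[int, int]]
) -> VariantClassSummary:
    """Percentages from explicit (count, denominator) pairs."""
    return VariantClassSummary(
        counts={k: c for k, (c, _) in counts.items()},
        denominators={k: d for k, (_, d) in counts.items()},
    )


@dataclass
class CdsGene:
    """Single-exon CDS model with its coding sequence (5'->3')."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_coding(pos: int, ref: str, alt: str, cds: CdsGene) -> str:
    """Synonymous / missense / nonsense for a SNP inside a CDS."""
    from Bio.Seq import Seq

    if cds.strand == "+":
        i = pos - cds.start
        r, a = ref, alt
    else:
        i = cds.end - pos
        r, a = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    if cds.seq[i] != r:
        raise ValueError(
            f"reference mismatch at {cds.gene_id} offset {i}: "
            f"CDS has {cds.seq[i]}, variant says {r}"
        )
    codon_i = i // 3
    old = cds.seq[codon_i * 3 : codon_i * 3 + 3]
    new = old[: i % 3] + a + old[i % 3 + 1 :]
    aa_old = str(Seq(old).translate())
    aa_new = str(Seq(new).translate())
    if aa_new == aa_old:
        return "synonymous"
    if aa_new == "*":
        return "nonsense"
    return "missense"


def classify_variants(
    table: GenotypeTable,
    catalog: GeneCatalog,
    flank: int = 5_000,
    cds_model: list[CdsGene] | None = None,
) -> VariantClassSummary:
    """Positional classification of every variant, plus coding classes for
    SNPs when a CDS model is given.

    Precedence on overlap: CDS > gene body (intron proxy) > flank
    (up/downstream) > intergenic.
    """
    n = table.n_sites
    snp = table.is_snp if table.is_snp is not None else np.ones(n, dtype=bool)
    n_snp = int(snp.sum())
    n_indel = n - n_snp
    ins = del_ = 0
    for j in np.flatnonzero(~snp):
        if len(table.alt[j]) > len(table.ref[j]):
            ins += 1
        else:
            del_ += 1

    classes = np.full(n, "intergenic", dtype=object)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in zip(catalog.chrom, catalog.start, catalog.end):
        by_chrom.setdefault(str(c), []).append((int(s), int(e)))
    cds_by_chrom: dict[str, list[CdsGene]] = {}
    for g in cds_model or []:
        cds_by_chrom.setdefault(g.chrom, []).append(g)
    coding_counts = {"synonymous": 0, "missense": 0, "nonsense": 0}
    for j in range(n):
        c, p = str(table.chrom[j]), int(table.pos[j])
        hit = None
        for g in cds_by_chrom.get(c, []):
            if g.start <= p <= g.end:
                hit = "in_orf"
                if snp[j]:
                    kind = classify_coding(p, str(table.ref[j]), str(table.alt[j]), g)
                    coding_counts[kind] += 1
                break
        if hit is None:
            for s, e in by_chrom.get(c, []):
                if s <= p <= e:
                    hit = "gene_body"
                    break
                if s - flank <= p <= e + flank:
                    hit = "up_downstream"  # keep scanning: gene body wins
            # flank assignment may be overridden by a later gene body; the
            # loop above breaks only on gene body, so re-check flanks
        classes[j] = hit or classes[j]

    def _pos_counts(mask):
        return {
            "in_orf": int(np.sum((classes == "in_orf") & mask)),
            "intronic": int(np.sum((classes == "gene_body") & mask)),
            "up_downstream": int(np.sum((classes == "up_downstream") & mask)),
            "intergenic": int(np.sum((classes == "intergenic") & mask)),
        }

    snp_pos = _pos_counts(snp)
    counts = {"snp": n_snp, "indel": n_indel}
    denoms = {"snp": n, "indel": n}
    if n_indel:
        counts.update(insertion=ins, deletion=del_)
        denoms.update(insertion=n_indel, deletion=n_indel)
    for k, v in snp_pos.items():
        counts[f"snp_{k}"] = v
        denoms[f"snp_{k}"] = n_snp if n_snp else 1
    if cds_model:
        n_coding = sum(coding_counts.values())
        for k, v in coding_counts.items():
            counts[k] = v
            denoms[k] = n_coding if n_coding else 1
    return VariantClassSummary(counts=counts, denominators=denoms)


@dataclass
class DensitySummary:
    variants_per_kb: float
    snp_per_100kb: float
    indel_per_100kb: float
    genome_bp: int


def density_summary(
    total_variants: int,
    snp_count: int,
    indel_count: int,
    genome_bp: int,
    window: int = 100_000,
) -> DensitySummary:
    """Genome-wide densities in the printed units (variants/kb rounded to
    one decimal; SNPs and INDELs per 100 kb)."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    return DensitySummary(
        variants_per_kb=round1(total_variants / (genome_bp / 1_000.0)),
        snp_per_100kb=round1(snp_count / (genome_bp / float(window))),
        indel_per_100kb=round1(indel_count / (genome_bp / float(window))),
        genome_bp=genome_bp,
    )


def density_track(table: GenotypeTable, window: int = 100_000) -> WindowTrack:
    """Variant counts per non-overlapping window (sums to the site total)."""
    chroms_out, starts_out, ends_out, ns_out = [], [], [], []
    for c, clen in chromosome_lengths(table).items():
        idx = np.flatnonzero(table.chrom == c)
        pos_c = table.pos[idx]
        starts, ends, _ = window_grid(clen, window, window)
        lo = np.searchsorted(pos_c, starts, side="left")
        hi = np.searchsorted(pos_c, ends, side="right")
        chroms_out.append(np.full(len(starts), c, dtype=object))
        starts_out.append(starts)
        ends_out.append(ends)
        ns_out.append(hi - lo)
    n = np.concatenate(ns_out)
    return WindowTrack(
        chrom=np.concatenate(chroms_out),
        start=np.concatenate(starts_out),
        end=np.concatenate(ends_out),
        n_sites=n.astype(np.int64),
        value=n.astype(float),
        name="variant-density",
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration


class StageError(RuntimeError):
    """A pipeline stage failed (named in the message)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    p = Path(path_or_dict)
    text = p.read_text()
    if p.suffix == ".toml":
        import tomllib

        return tomllib.loads(text)
    return json.loads(text)


DEFAULT_CONFIG = {
    "window": 10_000,
    "step": 1_000,
    "q": 0.95,
    "maf": 0.05,
    "max_missing": 0.10,
    "min_mean_depth": 5.0,
    "bootstrap": 0,
    "seed": 0,
}


def run_pipeline(config) -> Path:
    """Filter -> diversity/F_ST/XP-CLR -> LD -> sweep calling -> reports.

    ``config`` is a dict or a TOML/JSON path with keys ``vcf``, ``popmap``,
    ``gff``, ``outdir``, ``object_pop``, ``ref_pop``, optional ``lineages``
    (pi tracks; default: object and reference) and the knobs in
    ``DEFAULT_CONFIG``.  Writes CSV/BED/Newick artifacts plus a
    ``manifest.json`` with checksums and every threshold used; a rerun on
    identical inputs reproduces identical checksums.
    """
    cfg = {**DEFAULT_CONFIG, **load_config(config)}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in cfg.items()}, "stages": {}}
    artifacts: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = sorted(str(p.name) for p in out)
            artifacts.update({p.name: p for p in out})
            return out

        return deco

    state: dict = {}

    @stage("filter")
    def _filter():
        for key in ("vcf", "popmap", "gff"):
            if not Path(cfg[key]).exists():
                raise FileNotFoundError(cfg[key])
        table = io.read_vcf(cfg["vcf"])
        popmap = io.read_popmap(cfg["popmap"])
        popmap.validate_against(table.sample_ids)
        table = io.apply_hard_filters(table)
        table = io.apply_site_filters(
            table,
            max_missing=cfg["max_missing"],
            min_maf=cfg["maf"],
            min_mean_depth=cfg["min_mean_depth"],
        )
        state.update(table=table, popmap=popmap, catalog=io.read_gff(cfg["gff"]))
        p = outdir / "filtered_counts.json"
        p.write_text(
            json.dumps({"n_sites": table.n_sites, "n_samples": table.n_samples}) + "\n"
        )
        return [p]

    @stage("diversity")
    def _diversity():
        table, popmap = state["table"], state["popmap"]
        lineages = cfg.get("lineages") or [cfg["object_pop"], cfg["ref_pop"]]
        out = []
        state["pi_tracks"] = {}
        for lab in lineages:
            t = diversity.windowed_pi(
                table, popmap, lab, window=cfg["window"], step=cfg["step"]
            )
            state["pi_tracks"][lab] = t
            p = outdir / f"pi_{lab}.csv"
            io.write_track_csv(t, p)
            out.append(p)
        return out

    @stage("fst")
    def _fst():
        table, popmap = state["table"], state["popmap"]
        t = fst.windowed_fst(
            table,
            popmap,
            cfg["object_pop"],
            cfg["ref_pop"],
            window=cfg["window"],
            step=cfg["step"],
        )
        state["fst_track"] = t
        mean_fst, weighted = fst.global_fst(
            table, popmap, cfg["object_pop"], cfg["ref_pop"]
        )
        p1 = outdir / "fst_windows.csv"
        io.write_track_csv(t, p1)
        p2 = outdir / "fst_global.json"
        p2.write_text(
            json.dumps({"mean_fst": mean_fst, "weighted_fst": weighted}) + "\n"
        )
        return [p1, p2]

    @stage("xpclr")
    def _xpclr():
        table, popmap = state["table"], state["popmap"]
        scan = xpclr.xpclr_scan(table, popmap, cfg["object_pop"], cfg["ref_pop"])
        state["xpclr_track"] = scan
        p = outdir / "xpclr_grid.csv"
        io.write_track_csv(scan, p)
        return [p]

    @stage("ld")
    def _ld():
        table = state["table"]
        curve = ld.decay_curve(table, max_dist=100_000)
        p1 = outdir / "ld_decay.csv"
        curve.to_frame().to_csv(p1, index=False)
        pruned = ld.ld_prune(table)
        state["pruned"] = pruned
        p2 = outdir / "ld_prune_counts.json"
        p2.write_text(
            json.dumps(
                {"before": table.n_sites, "after": pruned.n_sites,
                 "max_r2": curve.max_r2, "half_max_interval": curve.half_max_interval}
            )
            + "\n"
        )
        return [p1, p2]

    @stage("structure")
    def _structure():
        pruned, popmap = state["pruned"], state["popmap"]
        res = phylo.pca(pruned)
        p1 = outdir / "pca.csv"
        df = pd.DataFrame(
            res.coords,
            index=res.sample_ids,
            columns=[f"PC{i+1}" for i in range(res.coords.shape[1])],
        )
        df.insert(0, "lineage", [popmap.assignments[s] for s in res.sample_ids])
        df.to_csv(p1, index_label="sample")
        p2 = outdir / "pca_variance.csv"
        pd.DataFrame({"pct": res.explained_pct}).to_csv(p2, index_label="component")
        if cfg["bootstrap"] > 0:
            njt = phylo.bootstrap_support(
                pruned, n_reps=cfg["bootstrap"], seed=cfg["seed"]
            )
        else:
            dist = diversity.p_distance_matrix(pruned, min_shared=1)
            njt = phylo.nj_tree(dist, pruned.sample_ids)
        p3 = outdir / "nj_tree.nwk"
        phylo.write_newick(njt, p3)
        return [p1, p2, p3]

    @stage("sweeps")
    def _sweeps():
        called = sweeps.call_sweeps(
            state["xpclr_track"], state["fst_track"], q=cfg["q"]
        )
        p1 = outdir / "sweep_regions.bed"
        io.write_bed(called, p1)
        summary = sweeps.summarize_sweeps(called)
        p2 = outdir / "sweep_summary.csv"
        summary.per_chrom.to_csv(p2, index=False)
        genes = sweeps.genes_in_regions(called, state["catalog"])
        p3 = outdir / "sweep_genes.txt"
        p3.write_text("".join(g + "\n" for g in genes))
        return [p1, p2, p3]

    manifest["checksums"] = {
        name: _sha256(path) for name, path in sorted(artifacts.items())
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir
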