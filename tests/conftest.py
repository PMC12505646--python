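import numpy as np
import pytest

from sweepscan import GenotypeTable, beet_panel_config, simulate


def make_table(
    dosage,
    pos=None,
    chrom="chr1",
    contig_len=None,
    depth=None,
    info=None,
    sample_ids=None,
    is_snp=None,
):
    """Small GenotypeTable from a dosage matrix (samples x sites)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    if pos is None:
        pos = np.arange(1, L + 1) * 100
    pos = np.asarray(pos, dtype=np.int64)
    if isinstance(chrom, str):
        chrom = np.full(L, chrom, dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    contigs = {}
    if contig_len is not None:
        for c in dict.fromkeys(chrom):
            contigs[c] = contig_len
    return GenotypeTable(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        chrom=chrom,
        pos=pos,
        ref=np.full(L, "A", dtype=object),
        alt=np.full(L, "T", dtype=object),
        dosage=dosage,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        info={} if info is None else {k: np.asarray(v, float) for k, v in info.items()},
        is_snp=np.ones(L, dtype=bool) if is_snp is None else np.asarray(is_snp, bool),
        contig_lengths=contigs,
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def beet_sim():
    """The packaged six-lineage fixture with three shared sweeps (seed 42)."""
    return simulate(beet_panel_config(seed=42))
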