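"""Population structure: genotype PCA and neighbor-joining phylogeny.

PCA follows the usual genotype convention: per-site mean centering, scaling
by sqrt(2*p(1-p)) (p = alternate-allele frequency), mean imputation of
missing dosages, then an eigendecomposition of the sample-sample covariance.

Trees are Bio.Phylo objects; NJ is the Saitou-Nei agglomeration with a
deterministic lowest-index tie-break, negative branch lengths clamped to 0
with the deficit moved to the sibling edge (raw mode available), and
bootstrap supports (%% of site-resampling replicates containing each
internal bipartition) stored as clade confidences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .diversity import p_distance_matrix
from .io import MISSING, GenotypeTable


@dataclass
class PcaResult:
    sample_ids: list[str]
    coords: np.ndarray  # samples x components
    explained_pct: np.ndarray  # per-component % of total variance
    n_dropped_sites: int = 0


def pca(table: GenotypeTable, n_components: int = 10) -> PcaResult:
    """Top principal components of the (preferably LD-pruned) dosage matrix.

    Sites with zero variance after mean imputation are dropped (counted in
    the result).  Explained-variance percentages are eigenvalue shares of
    the total variance and are non-increasing.
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs >=2 samples")
    D = table.dosage.astype(float)
    ok = table.dosage != MISSING
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, D, 0.0).sum(axis=0) / n_ok
    D = np.where(ok, D, mean[None, :])
    keep = (n_ok > 0) & (D.var(axis=0) > 0)
    n_dropped = int((~keep).sum())
    D = D[:, keep]
    mean = mean[keep]
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    X = (D - mean[None, :]) / scale[None, :]
    n, L = X.shape
    G = (X @ X.T) / L
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    k = min(n_components, n)
    coords = evecs[:, :k] * np.sqrt(evals[:k])[None, :]
    total = evals.sum()
    pct = 100.0 * evals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(list(table.sample_ids), coords, pct, n_dropped)


@dataclass
class NjTree:
    """A (possibly rooted) NJ tree plus its leaf order."""

    tree: Tree
    leaf_names: list[str]

    def terminals(self) -> list[str]:
        return [t.name for t in self.tree.get_terminals()]


def nj_tree(
    distance_matrix: np.ndarray, labels: list[str], clamp_negative: bool = True
) -> NjTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion break on the lowest (i, j) index pair.  With
    ``clamp_negative`` (default) a negative branch length is set to 0 and
    the deficit transferred to its sibling edge.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    if n < 2:
        raise ValueError("need >=2 taxa")
    nodes: list[Clade] = [Clade(name=str(l)) for l in labels]
    D = D.copy()
    active = list(range(n))

    def _pair_lengths(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best, bi, bj = np.inf, -1, -1
        for a in range(m - 1):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if q < best - 1e-15:
                    best, bi, bj = q, a, b
        i, j = active[bi], active[bj]
        dij = D[i, j]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _pair_lengths(li, lj)
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        new = Clade(clades=[nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for k_idx in active:
            if k_idx in (i, j):
                continue
            new_row[k_idx] = 0.5 * (D[i, k_idx] + D[j, k_idx] - dij)
        D = np.vstack([D, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        D = np.hstack([D, new_col[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        if clamp_negative:
            la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
        nodes[a].branch_length = la
        nodes[b].branch_length = lb
        nodes[c].branch_length = lc
        root = Clade(clades=[nodes[a], nodes[b], nodes[c]])
    else:
        a, b = active
        half = D[a, b] / 2.0
        nodes[a].branch_length = half
        nodes[b].branch_length = half
        root = Clade(clades=[nodes[a], nodes[b]])
    tree = Tree(root=root, rooted=False)
    return NjTree(tree, [str(l) for l in labels])


def _bipartitions(tree: Tree, leaf_names: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions, each normalised to the side not containing
    the first leaf name."""
    all_leaves = set(leaf_names)
    ref = leaf_names[0]
    out = set()
    for clade in tree.get_nonterminals():
        names = {t.name for t in clade.get_terminals()}
        if ref in names:
            names = all_leaves - names
        if 1 < len(names) < len(all_leaves) - 1:
            out.add(frozenset(names))
    return out


def bootstrap_support(
    table: GenotypeTable,
    n_reps: int = 100,
    seed: int | None = None,
    clamp_negative: bool = True,
) -> NjTree:
    """NJ tree from the full data with bootstrap supports.

    Sites are resampled with replacement per replicate; each replicate's NJ
    bipartitions are tallied, and every internal clade of the full-data tree
    receives the percentage of replicates containing its bipartition.
    """
    if table.n_samples < 4:
        raise ValueError("bootstrap needs >=4 samples")
    rng = np.random.default_rng(seed)
    labels = list(table.sample_ids)
    full = nj_tree(p_distance_matrix(table, min_shared=1), labels, clamp_negative)
    tally: dict[frozenset, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, table.n_sites, size=table.n_sites)
        rep = table.take_sites(idx)
        reptree = nj_tree(
            p_distance_matrix(rep, min_shared=1, allow_undefined=False),
            labels,
            clamp_negative,
        )
        for bp in _bipartitions(reptree.tree, labels):
            tally[bp] = tally.get(bp, 0) + 1
    all_leaves = set(labels)
    ref = labels[0]
    for clade in full.tree.get_nonterminals():
        names = {t.name for t in clade.get_terminals()}
        if ref in names:
            names = all_leaves - names
        if 1 < len(names) < len(all_leaves) - 1:
            clade.confidence = 100.0 * tally.get(frozenset(names), 0) / n_reps
    return full


def root_tree(njt: NjTree, outgroup_sample: str) -> NjTree:
    """Root on the midpoint of the outgroup's pendant edge.

    The input is treated as unrooted: the tree is flattened to an edge graph
    (suppressing any degree-2 node left by a previous rooting, summing its
    two edge lengths), the root is placed halfway along the outgroup's
    pendant edge, and the rooted tree rebuilt.  Rooting twice on the same
    leaf is therefore idempotent, and leaf-to-leaf path lengths are
    preserved exactly.
    """
    # edge graph: (neighbour, length, edge support).  Bootstrap support is a
    # property of the edge (bipartition), not of a node, so it must travel
    # with the edge when the tree is re-oriented.
    adj: dict[int, list[tuple[int, float, float | None]]] = {}
    names: dict[int, str | None] = {}

    def note(clade):
        names[id(clade)] = clade.name
        adj.setdefault(id(clade), [])

    note(njt.tree.root)
    for parent in njt.tree.find_clades(order="preorder"):
        for child in parent.clades:
            note(child)
            bl = child.branch_length or 0.0
            conf = None if child.is_terminal() else child.confidence
            adj[id(parent)].append((id(child), bl, conf))
            adj[id(child)].append((id(parent), bl, conf))
    # suppress degree-2 internal nodes (old rooting points)
    changed = True
    while changed:
        changed = False
        for node, nbrs in list(adj.items()):
            if len(nbrs) == 2 and names[node] is None:
                (a, la, ca), (b, lb, cb) = nbrs
                conf = ca if ca is not None else cb
                adj[a] = [e for e in adj[a] if e[0] != node] + [(b, la + lb, conf)]
                adj[b] = [e for e in adj[b] if e[0] != node] + [(a, la + lb, conf)]
                del adj[node]
                changed = True
    leaf = next(
        (n for n, name in names.items()
         if name == outgroup_sample and n in adj and len(adj[n]) == 1),
        None,
    )
    if leaf is None:
        raise KeyError(f"unknown leaf {outgroup_sample!r}")
    (u, pendant, pconf), = adj[leaf]

    def build(node: int, parent: int, length: float, conf) -> Clade:
        children = [
            build(n, node, l, c) for n, l, c in adj[node] if n != parent
        ]
        return Clade(
            name=names[node],
            confidence=None if not children else conf,
            branch_length=length,
            clades=children,
        )

    root = Clade(
        clades=[
            build(leaf, u, pendant / 2.0, None),
            build(u, leaf, pendant / 2.0, pconf),
        ]
    )
    return NjTree(Tree(root=root, rooted=True), njt.leaf_names)


def leaf_distances(njt: NjTree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (for conservation checks across rooting)."""
    terms = njt.tree.get_terminals()
    out = {}
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            key = tuple(sorted((a.name, b.name)))
            out[key] = njt.tree.distance(a, b)
    return out


def write_newick(njt: NjTree, path) -> None:
    Phylo.write(njt.tree, str(path), "newick", format_branch_length="%1.17g")


def read_newick(path) -> NjTree:
    tree = Phylo.read(str(path), "newick")
    return NjTree(tree, [t.name for t in tree.get_terminals()])
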