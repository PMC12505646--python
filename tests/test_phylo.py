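"""Genotype PCA and neighbor-joining phylogeny."""

import numpy as np
import pytest

import sweepscan as ss
from sweepscan.diversity import p_distance_matrix
from sweepscan.phylo import _bipartitions, leaf_distances, read_newick, write_newick
from conftest import make_table


def random_additive_tree(rng, n_taxa):
    """Random binary tree via sequential attachment; returns (labels, D)
    with D the exact path-length matrix (hence additive)."""
    import itertools

    # adjacency of an unrooted tree grown by subdividing random edges
    next_id = itertools.count()
    a, b = next(next_id), next(next_id)
    edges = {(a, b): float(rng.uniform(0.1, 1.0))}
    leaves = [a, b]
    for _ in range(n_taxa - 2):
        (u, v), _ = list(edges.items())[int(rng.integers(len(edges)))]
        w = next(next_id)  # subdivide edge (u, v) at w
        ln = edges.pop((u, v))
        t = float(rng.uniform(0.2, 0.8))
        edges[(u, w)] = ln * t
        edges[(w, v)] = ln * (1 - t)
        leaf = next(next_id)
        edges[(w, leaf)] = float(rng.uniform(0.1, 1.0))
        leaves.append(leaf)
    adj = {}
    for (u, v), ln in edges.items():
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    D = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    D = (D + D.T) / 2.0  # exact symmetry despite fp traversal order
    labels = [f"t{i}" for i in range(n_taxa)]
    return labels, D


class TestPca:
    def test_two_duplicate_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, 200).astype(np.int8)
        g2 = rng.integers(0, 3, 200).astype(np.int8)
        d = np.stack([g1, g1, g1, g2, g2, g2])
        res = ss.pca(make_table(d), n_components=3)
        pc1 = res.coords[:, 0]
        assert (pc1[:3].max() < pc1[3:].min()) or (pc1[:3].min() > pc1[3:].max())
        assert res.explained_pct[0] > res.explained_pct[1]

    def test_sample_permutation_permutes_coordinates(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(10, 300)).astype(np.int8)
        t = make_table(d)
        res = ss.pca(t, 4)
        perm = rng.permutation(10)
        t2 = t.take_samples([t.sample_ids[i] for i in perm])
        res2 = ss.pca(t2, 4)
        # same components up to sign
        for c in range(4):
            col = res.coords[perm, c]
            assert np.allclose(col, res2.coords[:, c]) or np.allclose(
                col, -res2.coords[:, c]
            )

    def test_explained_variance_well_formed(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(15, 400)).astype(np.int8)
        res = ss.pca(make_table(d), 10)
        assert np.all(np.diff(res.explained_pct) <= 1e-9)
        assert res.explained_pct.sum() <= 100.0 + 1e-9

    def test_four_population_silhouette(self):
        from sklearn.metrics import silhouette_score
        from sweepscan.simulate import PopulationSpec, SimConfig

        cfg = SimConfig(
            populations=[PopulationSpec("anc", None, 0.0, 0)]
            + [PopulationSpec(f"p{i}", "anc", 0.15, 12) for i in range(4)],
            chromosomes={"chr1": 400_000},
            snp_per_kb=5.0,
            missing_rate=0.0,
            mean_depth=30.0,
            seed=4,
        )
        table, pm, _ = ss.simulate(cfg)
        res = ss.pca(table, 2)
        labels = [pm.assignments[s] for s in res.sample_ids]
        assert silhouette_score(res.coords[:, :2], labels) > 0.3

    def test_zero_variance_sites_dropped(self):
        d = np.array([[0, 1, 2], [0, 2, 1], [0, 1, 1]], dtype=np.int8)
        res = ss.pca(make_table(d), 2)
        assert res.n_dropped_sites == 1


class TestNj:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        njt = ss.nj_tree(D, ["A", "B", "C"])
        bl = {t.name: t.branch_length for t in njt.tree.get_terminals()}
        # three-point formulas: a=(dAB+dAC-dBC)/2 etc.
        assert bl["A"] == pytest.approx(1.0)
        assert bl["B"] == pytest.approx(1.0)
        assert bl["C"] == pytest.approx(2.0)

    def test_recovers_additive_four_taxon_tree(self):
        # ((A:1,B:2):1,(C:3,D:1)): dAB=3 dAC=5 dAD=3 dBC=6 dBD=4 dCD=4
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        labels = list("ABCD")
        njt = ss.nj_tree(D, labels)
        assert leaf_distances(njt) == pytest.approx(
            {tuple(sorted((labels[i], labels[j]))): D[i, j]
             for i in range(4) for j in range(i + 1, 4)}
        )
        assert frozenset({"C", "D"}) in _bipartitions(njt.tree, labels) or \
            frozenset({"A", "B"}) in _bipartitions(njt.tree, labels)

    def test_additive_matrices_recovered_and_match_skbio(self):
        import skbio

        rng = np.random.default_rng(5)
        for n_taxa in (5, 7, 8):
            labels, D = random_additive_tree(rng, n_taxa)
            njt = ss.nj_tree(D, labels)
            # exact path-length recovery on additive input
            got = leaf_distances(njt)
            for i in range(n_taxa):
                for j in range(i + 1, n_taxa):
                    key = tuple(sorted((labels[i], labels[j])))
                    assert got[key] == pytest.approx(D[i, j], abs=1e-9)
            # independent implementation agrees on topology
            sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
            sk_bip = set()
            for node in sk.non_tips():
                names = frozenset(t.name for t in node.tips())
                if labels[0] in names:
                    names = frozenset(set(labels) - names)
                if 1 < len(names) < n_taxa - 1:
                    sk_bip.add(names)
            assert _bipartitions(njt.tree, labels) == sk_bip

    def test_constant_shift_preserves_topology(self):
        rng = np.random.default_rng(6)
        labels, D = random_additive_tree(rng, 6)
        before = _bipartitions(ss.nj_tree(D, labels).tree, labels)
        shifted = D + 0.5
        np.fill_diagonal(shifted, 0.0)
        after = _bipartitions(ss.nj_tree(shifted, labels).tree, labels)
        assert before == after

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            ss.nj_tree(D, ["A", "B"])

    def test_negative_branches_clamped_by_default(self):
        D = np.array(
            [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.5, 0.5],
             [0.5, 0.5, 0, 0.01], [0.5, 0.5, 0.01, 0]]
        )
        njt = ss.nj_tree(D, list("ABCD"))
        for cl in njt.tree.find_clades():
            assert cl.branch_length is None or cl.branch_length >= 0


class TestBootstrapAndRooting:
    def _clean_table(self, seed=7):
        from sweepscan.simulate import PopulationSpec, SimConfig

        cfg = SimConfig(
            populations=[PopulationSpec("anc", None, 0.0, 0)]
            + [PopulationSpec(f"p{i}", "anc", 0.25, 4) for i in range(4)],
            chromosomes={"chr1": 300_000},
            snp_per_kb=5.0,
            missing_rate=0.0,
            mean_depth=30.0,
            seed=seed,
        )
        table, pm, _ = ss.simulate(cfg)
        return table, pm

    def test_population_clades_strongly_supported(self):
        table, pm = self._clean_table()
        njt = ss.bootstrap_support(table, n_reps=50, seed=1)
        by_pop = {
            lab: frozenset(pm.samples_for(lab)) for lab in ("p1", "p2", "p3")
        }
        supports = {}
        labels = list(table.sample_ids)
        all_leaves = set(labels)
        for clade in njt.tree.get_nonterminals():
            names = {t.name for t in clade.get_terminals()}
            if labels[0] in names:
                names = all_leaves - names
            supports[frozenset(names)] = clade.confidence
        for lab, members in by_pop.items():
            assert supports.get(members, 0) >= 90, lab

    def test_seeded_determinism(self):
        table, _ = self._clean_table()
        a = ss.bootstrap_support(table, n_reps=20, seed=5)
        b = ss.bootstrap_support(table, n_reps=20, seed=5)
        ca = sorted(c.confidence for c in a.tree.get_nonterminals()
                    if c.confidence is not None)
        cb = sorted(c.confidence for c in b.tree.get_nonterminals()
                    if c.confidence is not None)
        assert ca == cb

    def test_rooting_idempotent_and_conserves_paths(self):
        table, _ = self._clean_table()
        small = table.take_samples(table.sample_ids[:8])
        njt = ss.nj_tree(p_distance_matrix(small, min_shared=1), small.sample_ids)
        r1 = ss.root_tree(njt, small.sample_ids[0])
        r2 = ss.root_tree(r1, small.sample_ids[0])
        d0, d1, d2 = (leaf_distances(t) for t in (njt, r1, r2))
        for k in d0:
            assert d1[k] == pytest.approx(d0[k], abs=1e-9)
            assert d2[k] == pytest.approx(d1[k], abs=1e-9)

    def test_rooting_preserves_bipartition_supports(self):
        table, _ = self._clean_table()
        njt = ss.bootstrap_support(table.take_samples(table.sample_ids[:12]),
                                   n_reps=20, seed=3)
        labels = njt.leaf_names
        all_leaves = set(labels)

        def support_map(t):
            out = {}
            for clade in t.tree.get_nonterminals():
                names = {x.name for x in clade.get_terminals()}
                if labels[0] in names:
                    names = all_leaves - names
                if 1 < len(names) < len(all_leaves) - 1 and clade.confidence is not None:
                    out[frozenset(names)] = clade.confidence
            return out

        before = support_map(njt)
        after = support_map(ss.root_tree(njt, labels[-1]))
        for bp, conf in before.items():
            assert after.get(bp) == pytest.approx(conf)

    def test_root_three_taxa(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        rooted = ss.root_tree(ss.nj_tree(D, ["A", "B", "C"]), "A")
        kids = rooted.tree.root.clades
        names = sorted(
            "+".join(sorted(t.name for t in c.get_terminals())) for c in kids
        )
        assert names == ["A", "B+C"]

    def test_unknown_outgroup_errors(self):
        D = np.array([[0, 1], [1, 0]], float)
        with pytest.raises(KeyError):
            ss.root_tree(ss.nj_tree(D, ["A", "B"]), "Z")

    def test_newick_round_trip(self, tmp_path):
        table, _ = self._clean_table()
        njt = ss.bootstrap_support(table.take_samples(table.sample_ids[:10]),
                                   n_reps=10, seed=2)
        p = tmp_path / "t.nwk"
        write_newick(njt, p)
        back = read_newick(p)
        assert sorted(back.terminals()) == sorted(njt.terminals())
        d0, d1 = leaf_distances(njt), leaf_distances(back)
        for k in d0:
            assert d1[k] == pytest.approx(d0[k], abs=1e-9)
        conf0 = sorted(c.confidence for c in njt.tree.get_nonterminals()
                       if c.confidence is not None)
        conf1 = sorted(c.confidence for c in back.tree.get_nonterminals()
                       if c.confidence is not None)
        assert conf0 == pytest.approx(conf1)
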