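"""Distance matrices, neighbor joining, bootstrap supports, genome groups."""

import dendropy
import numpy as np
import pytest

from retroclock import (
    Alignment,
    GroupSpec,
    SimConfig,
    bootstrap_support,
    classify_genome_groups,
    k2p_matrix,
    neighbor_joining,
    simulate_family,
)
from retroclock.phylo import DistanceMatrix, Tree, TreeNode


def random_additive_matrix(n_taxa, rng):
    """Random binary tree with positive branch lengths -> (labels, D, splits)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=l) for l in labels]
    for nd in nodes:
        nd.length = rng.uniform(0.05, 1.0)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=rng.uniform(0.05, 1.0))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add(n)
    tree = Tree(root)
    dm = tree.path_lengths()
    return dm, tree.bipartitions()


class TestK2PMatrix:
    def _aln(self, *rows):
        return Alignment(tuple((f"s{i}", r) for i, r in enumerate(rows)))

    def test_identical_rows_give_zero_matrix(self):
        m = k2p_matrix(self._aln("ACGTACGT", "ACGTACGT", "ACGTACGT"))
        assert np.all(m.d == 0)

    def test_hand_computed_transition_distance(self):
        # one A<->G difference over 4 sites: -0.5 ln(0.5) = 0.346574
        m = k2p_matrix(self._aln("AAAA", "GAAA", "AAAA"))
        assert m.d[0, 1] == pytest.approx(0.3465736, abs=1e-6)
        assert m.d[1, 2] == pytest.approx(0.3465736, abs=1e-6)
        assert m.d[0, 2] == 0.0

    def test_pairwise_equals_complete_when_gap_free(self, rng):
        from retroclock.synthetic_data import evolve_copy, random_sequence

        cfg = SimConfig()
        anc = random_sequence(200, cfg, rng)
        rows = tuple(
            (f"s{i}", evolve_copy(anc, 2e6, cfg, rng)) for i in range(4)
        )
        aln = Alignment(rows)
        assert np.allclose(k2p_matrix(aln, "pairwise").d,
                           k2p_matrix(aln, "complete").d)

    def test_deletion_modes_differ_with_gaps(self):
        aln = self._aln("ACGTAC-T", "ACGTACGT", "AC--ACGT")
        pw = k2p_matrix(aln, "pairwise")
        co = k2p_matrix(aln, "complete")
        assert pw.d[0, 1] == 0.0 and co.d[0, 1] == 0.0

    def test_saturated_pair_reported_by_name(self):
        aln = self._aln("AAAAAAAAAA", "GGGGGGGGGG", "AAAAAAAAAA")
        with pytest.raises(ValueError, match="s0/s1"):
            k2p_matrix(aln)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:1):1,(C:1,D:1)): d(A,B)=d(C,D)=2, cross distances 3
        labels = ("A", "B", "C", "D")
        d = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
                     dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert all(lengths[x] == pytest.approx(1.0) for x in labels)
        internal = [n for n in tree.root.walk()
                    if n is not tree.root and not n.is_tip()]
        assert len(internal) == 1 and internal[0].length == pytest.approx(1.0)

    def test_zero_matrix_star_with_zero_lengths(self):
        m = DistanceMatrix(("A", "B", "C"), np.zeros((3, 3)))
        tree = neighbor_joining(m)
        assert all(t.length == 0.0 for t in tree.tips())
        assert tree.bipartitions() == set()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    def test_recovers_generating_topology_on_additive_matrices(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 9))
            dm, true_splits = random_additive_matrix(n, rng)
            tree = neighbor_joining(dm)
            assert tree.bipartitions() == true_splits, f"trial {trial}"

    def test_path_lengths_reproduce_additive_input(self, rng):
        for _ in range(10):
            dm, _ = random_additive_matrix(int(rng.integers(4, 9)), rng)
            tree = neighbor_joining(dm)
            out = tree.path_lengths()
            order = [out.labels.index(l) for l in dm.labels]
            assert np.allclose(out.d[np.ix_(order, order)], dm.d, atol=1e-9)

    def test_invariant_to_label_permutation(self, rng):
        dm, _ = random_additive_matrix(7, rng)
        perm = rng.permutation(dm.n)
        dm2 = DistanceMatrix(tuple(dm.labels[i] for i in perm),
                             dm.d[np.ix_(perm, perm)])
        assert neighbor_joining(dm).bipartitions() == \
            neighbor_joining(dm2).bipartitions()

    def test_agrees_with_dendropy_on_additive_matrices(self, rng):
        """Independent NJ implementation recovers the same splits."""
        for _ in range(5):
            dm, _ = random_additive_matrix(6, rng)
            tree = neighbor_joining(dm)
            csv = "," + ",".join(dm.labels) + "\n" + "\n".join(
                dm.labels[i] + "," + ",".join(str(x) for x in dm.d[i])
                for i in range(dm.n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=csv.splitlines(True).__iter__(), delimiter=",")
            dtree = pdm.nj_tree()
            dtree.encode_bipartitions()
            d_splits = set()
            taxa = frozenset(dm.labels)
            for edge in dtree.preorder_edge_iter():
                if edge.head_node.is_leaf() or edge.tail_node is None:
                    continue
                side = frozenset(
                    lf.taxon.label for lf in edge.head_node.leaf_iter())
                if 1 < len(side) < len(taxa) - 1:
                    other = taxa - side
                    d_splits.add(min((side, other),
                                     key=lambda s: (len(s), tuple(sorted(s)))))
            mine = {min((s, taxa - s), key=lambda s: (len(s), tuple(sorted(s))))
                    for s in tree.bipartitions()}
            assert mine == d_splits


class TestBootstrap:
    def _family_alignment(self, rng, n_cols_factor=1):
        cfg = SimConfig(domain_len=200 * n_cols_factor)
        groups = [GroupSpec("g1", "B", 2, 8e6, 0.5e6),
                  GroupSpec("g2", "D", 2, 8e6, 0.5e6)]
        aln, _, _ = simulate_family(cfg, groups, rng)
        return aln

    def test_strong_split_has_high_support(self, rng):
        aln = self._family_alignment(rng)
        tree = bootstrap_support(aln, n_reps=100, seed=7)
        supports = {n.support for n in tree.root.walk()
                    if n is not tree.root and not n.is_tip()}
        assert max(supports) >= 95

    def test_single_replicate_supports_are_0_or_100(self, rng):
        aln = self._family_alignment(rng)
        tree = bootstrap_support(aln, n_reps=1, seed=3)
        for n in tree.root.walk():
            if n is not tree.root and not n.is_tip():
                assert n.support in (0, 100)

    def test_same_seed_reproduces_supports(self, rng):
        aln = self._family_alignment(rng)
        t1 = bootstrap_support(aln, n_reps=25, seed=11)
        t2 = bootstrap_support(aln, n_reps=25, seed=11)
        s1 = sorted(n.support for n in t1.root.walk()
                    if n is not t1.root and not n.is_tip())
        s2 = sorted(n.support for n in t2.root.walk()
                    if n is not t2.root and not n.is_tip())
        assert s1 == s2


def caterpillar(tip_specs):
    """Build a ladder tree from [(name, ...)] with 0.1 branch lengths."""
    nodes = [TreeNode(name=n, length=0.1) for n in tip_specs]
    while len(nodes) > 3:
        parent = TreeNode(length=0.1)
        parent.add(nodes.pop())
        parent.add(nodes.pop())
        nodes.append(parent)
    root = TreeNode()
    for n in nodes:
        root.add(n)
    return Tree(root)


class TestGenomeGroups:
    def test_pure_clades_are_genome_specific(self):
        tips_b = [f"b{i}" for i in range(6)]
        tips_d = [f"d{i}" for i in range(6)]
        # two pure 6-tip clades hanging off the root
        root = TreeNode()
        for tips in (tips_b, tips_d):
            cl = caterpillar(tips).root
            cl.length = 0.5
            root.add(cl)
        root.add(TreeNode(name="out", length=0.5))
        tree = Tree(root)
        labels = {t: "B" for t in tips_b} | {t: "D" for t in tips_d} | {"out": "A"}
        groups = classify_genome_groups(tree, labels, 0.9, 5)
        by_label = {g.group_label: g for g in groups}
        assert by_label["B-specific"].members == frozenset(tips_b)
        assert by_label["D-specific"].members == frozenset(tips_d)
        assert by_label["mixed"].members == {"out"}

    def test_impure_clade_fails_purity_threshold(self):
        tips = [f"b{i}" for i in range(6)] + ["d_intruder"]
        root = TreeNode()
        cl = caterpillar(tips).root
        cl.length = 0.5
        root.add(cl)
        root.add(TreeNode(name="x1", length=0.5))
        root.add(TreeNode(name="x2", length=0.5))
        tree = Tree(root)
        labels = {t: "B" for t in tips[:6]} | {"d_intruder": "D",
                                               "x1": "D", "x2": "D"}
        groups = classify_genome_groups(tree, labels, 0.9, 5)
        # purity 6/7 = 0.857 < 0.9: the full clade is not B-specific
        assert not any(g.group_label == "B-specific"
                       and g.members == frozenset(tips) for g in groups)

    def test_no_clade_meets_min_size_yields_single_mixed_group(self):
        tree = caterpillar(["a1", "a2", "b1", "b2"])
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        groups = classify_genome_groups(tree, labels, 0.9, 5)
        assert len(groups) == 1
        assert groups[0].group_label == "mixed"
        assert groups[0].members == {"a1", "a2", "b1", "b2"}

    def test_planted_groups_recovered_end_to_end(self, rng):
        cfg = SimConfig(domain_len=600)
        groups = [GroupSpec("gB", "B", 7, 6e6, 1.5e6),
                  GroupSpec("gD", "D", 7, 6e6, 1.5e6),
                  GroupSpec("gM", "A", 5, 2e6, 2.0e6)]
        aln, labels, truths = simulate_family(cfg, groups, rng)
        tree = neighbor_joining(k2p_matrix(aln))
        got = classify_genome_groups(tree, labels, 0.9, 5)
        planted = {}
        for t in truths:
            planted.setdefault(t.group_id, set()).add(t.element_id)
        got_sets = {frozenset(g.members) for g in got}
        for members in planted.values():
            assert frozenset(members) in got_sets
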