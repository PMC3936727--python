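"""Column selection, distances, neighbor joining, bootstrap, monophyly."""

import math
import random

import numpy as np
import pytest

from crisprpam.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloUsageError,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    robinson_foulds,
    select_informative_columns,
)

from _oracles import (
    random_additive_tree,
    tree_graph_bipartitions,
    tree_graph_distances,
)


def _aln(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Alignment(tuple(ids), tuple(rows))


class TestColumnSelection:
    def test_all_gap_column_removed(self):
        aln = _aln(["A-C", "G-C", "T-A"])
        kept_aln, kept = select_informative_columns(aln, require_variation=False)
        assert kept == [0, 2]
        assert kept_aln.rows == ("AC", "GC", "TA")

    def test_gapless_variable_alignment_unchanged(self):
        aln = _aln(["ACG", "GCA", "TAA"])
        kept_aln, kept = select_informative_columns(aln)
        assert kept == [0, 1, 2] and kept_aln.rows == aln.rows

    def test_kept_count_matches_per_column_scan(self):
        rng = random.Random(5)
        rows = ["".join(rng.choice("ACGT-") for _ in range(60)) for _ in range(6)]
        aln = _aln(rows)
        _, kept = select_informative_columns(aln, max_gap_fraction=0.5)
        expected = 0
        for i in range(60):
            col = [r[i] for r in rows]
            gapfrac = col.count("-") / 6
            residues = {c for c in col if c != "-"}
            if gapfrac <= 0.5 and len(residues) >= 2:
                expected += 1
        assert len(kept) == expected

    def test_zero_columns_is_an_error(self):
        with pytest.raises(PhyloUsageError, match="relax"):
            select_informative_columns(_aln(["AAA", "AAA", "AAA"]))


class TestDistances:
    def test_identical_pair_is_zero(self):
        dm = distance_matrix(_aln(["ACGT", "ACGT", "TTTT"]))
        assert dm.d[0, 1] == 0.0

    def test_poisson_closed_form(self):
        dm = distance_matrix(_aln(["AACC", "AAGG", "CCGG"]), model="poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.5))

    def test_hand_computed_p_distances(self):
        # s0/s1 differ at 1 of 4 shared; s0/s2 at 2 of 3 (one gapped column)
        aln = _aln(["ACGT", "ACGA", "AT-A"])
        dm = distance_matrix(aln, model="p")
        assert dm.d[0, 1] == pytest.approx(0.25)
        assert dm.d[0, 2] == pytest.approx(2 / 3)

    def test_no_comparable_positions_is_an_error(self):
        with pytest.raises(PhyloUsageError, match="comparable"):
            distance_matrix(_aln(["A--", "-C-", "--G"]), model="p")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"), np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    @pytest.mark.parametrize("case", range(25))
    def test_exact_on_additive_matrices(self, case):
        rng = random.Random(4000 + case)
        g, labels = random_additive_tree(6, rng)
        d = tree_graph_distances(g, labels)
        tree = nj_tree(DistanceMatrix(tuple(labels), d))
        assert tree.bipartitions() == tree_graph_bipartitions(g, labels)
        paths = tree.path_lengths()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    key = (a, b) if a < b else (b, a)
                    assert paths[key] == pytest.approx(d[i, j], abs=1e-9)

    def test_first_join_is_argmin_of_q(self):
        rng = random.Random(13)
        n = 7
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = rng.uniform(0.5, 3.0)
        labels = tuple(f"t{i}" for i in range(n))
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        best = min(
            ((q[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
            key=lambda t: t[0],
        )
        pair = {labels[best[1]], labels[best[2]]}
        tree = nj_tree(DistanceMatrix(labels, d))
        cherries = [
            set(node.leaf_labels())
            for node in tree._internal_nodes()
            if len(node.leaf_labels()) == 2
        ]
        assert pair in cherries

    def test_label_permutation_changes_nothing(self):
        rng = random.Random(14)
        g, labels = random_additive_tree(6, rng)
        d = tree_graph_distances(g, labels)
        tree1 = nj_tree(DistanceMatrix(tuple(labels), d))
        perm = list(range(6))
        rng.shuffle(perm)
        d2 = d[np.ix_(perm, perm)]
        tree2 = nj_tree(DistanceMatrix(tuple(labels[i] for i in perm), d2))
        assert tree1.newick() == tree2.newick()

    def test_newick_parses_with_dendropy(self):
        import dendropy

        rng = random.Random(15)
        g, labels = random_additive_tree(7, rng)
        tree = nj_tree(DistanceMatrix(tuple(labels), tree_graph_distances(g, labels)))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(labels)

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(PhyloUsageError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0]], float)))


class TestMonophyly:
    def _tree(self, seed=16, n=8):
        rng = random.Random(seed)
        g, labels = random_additive_tree(n, rng)
        return nj_tree(DistanceMatrix(tuple(labels), tree_graph_distances(g, labels))), g, labels

    def test_trivial_groups(self):
        tree, _, labels = self._tree()
        assert tree.check_monophyly(set(labels))
        assert tree.check_monophyly({labels[0]})

    def test_unknown_label_is_an_error(self):
        tree, _, _ = self._tree()
        with pytest.raises(PhyloUsageError):
            tree.check_monophyly({"nope"})

    @pytest.mark.parametrize("case", range(10))
    def test_agrees_with_exhaustive_bipartition_enumeration(self, case):
        rng = random.Random(6000 + case)
        g, labels = random_additive_tree(rng.randint(5, 10), rng)
        tree = nj_tree(DistanceMatrix(tuple(labels), tree_graph_distances(g, labels)))
        bips = tree_graph_bipartitions(g, labels)
        all_leaves = frozenset(labels)
        anchor = min(all_leaves)
        for _ in range(30):
            k = rng.randint(1, len(labels))
            group = frozenset(rng.sample(labels, k))
            canon = group if anchor not in group else all_leaves - group
            expected = len(group) in (1, len(labels) - 1, len(labels)) or canon in bips
            assert tree.check_monophyly(group) == expected


class TestBootstrap:
    def _family_alignment(self):
        rng = random.Random(17)
        baseA = "".join(rng.choice("ACDEFGHIKL") for _ in range(120))
        baseB = "".join(rng.choice("MNPQRSTVWY") for _ in range(120))
        rows, ids = [], []
        for fam, base in (("A", baseA), ("B", baseB)):
            for m in range(3):
                seq = list(base)
                for _ in range(4):
                    seq[rng.randrange(120)] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
                rows.append("".join(seq))
                ids.append(f"{fam}{m}")
        return Alignment(tuple(ids), tuple(rows))

    def test_separated_families_get_full_support(self):
        aln = self._family_alignment()
        tree = bootstrap_support(aln, B=30, seed=1)
        assert tree.check_monophyly({"A0", "A1", "A2"})
        family_bip = frozenset({"B0", "B1", "B2"})
        supports = {}
        stack = list(tree.root.children)
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            if not node.is_leaf and node.support is not None:
                side = node.leaf_labels()
                if "A0" in side:
                    side = tree.leaves - side
                supports[frozenset(side)] = node.support
        assert supports[family_bip] == pytest.approx(1.0)

    def test_same_seed_reproduces_supports(self):
        aln = self._family_alignment()
        t1 = bootstrap_support(aln, B=10, seed=5)
        t2 = bootstrap_support(aln, B=10, seed=5)
        assert t1.newick() == t2.newick()

    def test_single_replicate_supports_are_zero_or_one(self):
        aln = self._family_alignment()
        tree = bootstrap_support(aln, B=1, seed=2)
        supports = [
            n.support
            for n in tree._internal_nodes()
            if n.support is not None
        ]
        assert supports and all(s in (0.0, 1.0) for s in supports)

    def test_b_below_one_rejected(self):
        with pytest.raises(PhyloUsageError):
            bootstrap_support(self._family_alignment(), B=0, seed=0)


def test_robinson_foulds_zero_on_self():
    rng = random.Random(18)
    g, labels = random_additive_tree(6, rng)
    tree = nj_tree(DistanceMatrix(tuple(labels), tree_graph_distances(g, labels)))
    assert robinson_foulds(tree, tree) == 0
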