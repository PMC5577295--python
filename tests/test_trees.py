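import itertools

import networkx as nx
import numpy as np
import pytest
from skbio import TreeNode

from barcodegap.core_io import AlignedSequenceSet
from barcodegap.distances import DistanceMatrix, distance_matrix
from barcodegap.trees import (
    MatrixError,
    bootstrap_support,
    monophyly_report,
    nj_tree,
    tree_from_newick,
    tree_to_newick,
    upgma_tree,
)


def dm(labels, matrix):
    return DistanceMatrix(list(labels), np.asarray(matrix, dtype=float))


def tip_distances(tree):
    """Path distances between tips as a dict keyed by frozenset pairs."""
    d = tree.tip_tip_distances()
    out = {}
    for i, a in enumerate(d.ids):
        for j, b in enumerate(d.ids):
            if i < j:
                out[frozenset((a, b))] = d[a, b]
    return out


def random_binary_tree(rng, labels):
    """Random rooted binary topology with branch lengths in [0.1, 1]."""
    def build(names):
        if len(names) == 1:
            return TreeNode(name=names[0], length=round(rng.uniform(0.1, 1.0), 3))
        k = int(rng.integers(1, len(names)))
        left = build(names[:k])
        right = build(names[k:])
        node = TreeNode(children=[left, right],
                        length=round(rng.uniform(0.1, 1.0), 3))
        return node

    names = list(labels)
    rng.shuffle(names)
    root = build(names)
    root.length = None
    return root


def matrix_from_tree(tree):
    d = tree.tip_tip_distances()
    labels = sorted(d.ids)
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = d[a, b]
    return dm(labels, m)


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # matrix from tree (A:1,B:2)|1|(C:3,D:4)
        m = dm("ABCD", [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]])
        tree = nj_tree(m)
        dists = tip_distances(tree)
        assert dists[frozenset("AB")] == pytest.approx(3)
        assert dists[frozenset("CD")] == pytest.approx(7)
        assert dists[frozenset("AC")] == pytest.approx(5)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        # AB|CD split present
        sides = [frozenset(x.name for x in n.tips())
                 for n in tree.non_tips(include_self=False)]
        assert frozenset("AB") in sides or frozenset("CD") in sides

    def test_three_taxon_closed_form(self):
        m = dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(m)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_all_zero_matrix(self):
        tree = nj_tree(dm("ABCD", np.zeros((4, 4))))
        assert all(t.length == 0.0 for t in tree.traverse(include_self=False))

    def test_undefined_entry_rejected_naming_pair(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(MatrixError, match="A.*B"):
            nj_tree(dm("ABC", m))

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(0)
        for rep in range(30):
            n = int(rng.integers(4, 13))
            src = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            matrix = matrix_from_tree(src)
            rebuilt = nj_tree(matrix)
            d = tip_distances(rebuilt)
            for pair, ref in tip_distances(src).items():
                assert d[pair] == pytest.approx(ref, abs=1e-9)

    def test_agrees_with_skbio_topology(self):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(4)
        src = random_binary_tree(rng, [f"t{i}" for i in range(8)])
        matrix = matrix_from_tree(src)
        ours = nj_tree(matrix)
        theirs = skbio_nj(SkDM(matrix.values, matrix.labels))
        assert ours.compare_rfd(theirs) == 0.0


class TestUPGMA:
    def test_hand_agglomeration(self):
        tree = upgma_tree(dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        assert tree_to_newick(tree).strip() == "(C:2.0,(A:1.0,B:1.0):1.0);"

    def test_two_taxa(self):
        tree = upgma_tree(dm("AB", [[0, 0.5], [0.5, 0]]))
        assert {t.name: t.length for t in tree.tips()} == {"A": 0.25, "B": 0.25}

    def test_ultrametric_input_recovered_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            # random ultrametric: random rooted tree with equal root-tip depth
            src = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            for tip in src.tips():  # stretch tips to equalize depths
                depth = sum(x.length or 0 for x in [tip] + list(tip.ancestors())
                            if x.length)
                tip.length += 10.0 - depth
            matrix = matrix_from_tree(src)
            rebuilt = upgma_tree(matrix)
            d = tip_distances(rebuilt)
            for pair, ref in tip_distances(src).items():
                assert d[pair] == pytest.approx(ref, abs=1e-9)

    def test_root_to_tip_distances_equal(self):
        rng = np.random.default_rng(3)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = upgma_tree(dm([f"t{i}" for i in range(6)], m))
        depths = {
            t.name: sum(x.length for x in [t] + list(t.ancestors())
                        if x.length is not None)
            for t in tree.tips()
        }
        vals = list(depths.values())
        assert max(vals) - min(vals) < 1e-9

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(10)
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(7)]
        tree = upgma_tree(dm(labels, m))
        ours = tip_distances(tree)
        ref = squareform(cophenet(average(squareform(m))))
        for i, j in itertools.combinations(range(7), 2):
            assert ours[frozenset((labels[i], labels[j]))] == pytest.approx(
                ref[i, j], abs=1e-9
            )


class TestBootstrap:
    def _two_cluster_alignment(self):
        return AlignedSequenceSet.from_records(
            [(f"a{i}", "A", "", "A" * 40) for i in range(3)]
            + [(f"b{i}", "B", "", "A" * 30 + "G" * 10) for i in range(3)]
        )

    def test_clean_split_gets_full_support(self):
        # resampling cannot break a zero-vs-large split: the edge separating
        # the two clusters must appear in every replicate
        tree = bootstrap_support(self._two_cluster_alignment(), "nj",
                                 replicates=100, seed=1)
        split_supports = [
            n.support for n in tree.non_tips(include_self=False)
            if frozenset(t.name for t in n.tips()) in (
                frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})
            )
        ]
        assert split_supports and all(s == 100.0 for s in split_supports)

    def test_deterministic_for_fixed_seed(self, small_genus):
        aln = small_genus.alignment
        t1 = bootstrap_support(aln, "nj", replicates=20, seed=7)
        t2 = bootstrap_support(aln, "nj", replicates=20, seed=7)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_supports_within_range(self, small_genus):
        tree = bootstrap_support(small_genus.alignment, "upgma",
                                 replicates=20, seed=3)
        for n in tree.non_tips(include_self=False):
            if getattr(n, "support", None) is not None:
                assert 0.0 <= n.support <= 100.0


class TestNewick:
    def test_round_trip_topology_lengths_supports(self, small_genus):
        tree = bootstrap_support(small_genus.alignment, "nj",
                                 replicates=10, seed=2)
        text = tree_to_newick(tree)
        back = tree_from_newick(text)
        assert back.compare_rfd(tree) == 0.0
        ours = tip_distances(tree)
        for pair, v in tip_distances(back).items():
            assert v == pytest.approx(ours[pair], abs=1e-9)
        supports = sorted(
            n.support for n in back.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        )
        ref = sorted(
            n.support for n in tree.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        )
        assert supports == pytest.approx(ref)


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

def monophyly_oracle(tree, species_map, species):
    """Independent edge-removal oracle using a networkx graph of the tree."""
    g = nx.Graph()
    for node in tree.traverse(include_self=True):
        for child in node.children:
            g.add_edge(id(node), id(child))
    tip_nodes = {id(t): t.name for t in tree.tips()}
    target = {t for t, sp in ((t.name, species_map[t.name]) for t in tree.tips())
              if sp == species}
    if len(target) <= 1 or len(target) == len(tip_nodes):
        return True
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        for comp in nx.connected_components(h):
            tips = {tip_nodes[n] for n in comp if n in tip_nodes}
            if tips == target:
                return True
    return False


class TestMonophyly:
    def test_simple_split(self):
        tree = tree_from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        rep = monophyly_report(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert rep.per_species == {"A": True, "B": True}
        assert rep.discrimination_rate == 1.0

    def test_interleaved_species_fail(self):
        tree = tree_from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        rep = monophyly_report(
            tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, rooted=True
        )
        assert rep.per_species == {"A": False, "B": False}

    def test_unrooted_complement_side_counts(self):
        # species B occupies the complement of clade {a1,a2}
        tree = tree_from_newick("((a1:1,a2:1):1,b1:1,b2:1);")
        rep = monophyly_report(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert rep.per_species["B"] is True

    def test_singleton_policies(self):
        tree = tree_from_newick("((a1:1,b1:1):1,(a2:1,c1:1):1);")
        sp = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        inc = monophyly_report(tree, sp, singleton_policy="count_as_success")
        exc = monophyly_report(tree, sp, singleton_policy="exclude")
        assert inc.n_species_counted == 3 and inc.n_monophyletic == 2
        assert exc.n_species_counted == 1 and exc.n_monophyletic == 0

    def test_unmapped_tip_rejected(self):
        tree = tree_from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(KeyError):
            monophyly_report(tree, {"a": "A", "b": "B"})

    def test_agrees_with_edge_removal_oracle_on_random_trees(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            tree = random_binary_tree(rng, [f"t{i}" for i in range(n)])
            species_map = {f"t{i}": f"sp{rng.integers(0, 3)}" for i in range(n)}
            rep = monophyly_report(tree, species_map)
            for sp, got in rep.per_species.items():
                assert got == monophyly_oracle(tree, species_map, sp), (
                    tree.ascii_art(), species_map, sp
                )
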