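"""Distances, neighbor joining, bootstrap supports, rooting."""

import numpy as np
import pytest

from phylofate import (
    ClusterAlignment,
    bootstrap_support,
    distance_matrix,
    filter_by_support,
    nj_tree,
    parse_newick,
    root_at_outgroup,
)
from phylofate.njtree import DistanceError, Node, bipartitions, tree_distances

from conftest import mutate, random_seq


def _aln(rows, ids=None, species=None):
    return ClusterAlignment(
        cluster_id="t",
        ids=ids or [f"s{i}" for i in range(len(rows))],
        species=species or [""] * len(rows),
        rows=rows,
    )


class TestDistanceMatrix:
    def test_identical_rows_zero(self, rng):
        seq = random_seq(rng, 120)
        ids, D = distance_matrix(_aln([seq] * 3))
        assert np.allclose(D, 0)

    def test_p_distance_definition(self, rng):
        seq = random_seq(rng, 100)
        rows = [seq, mutate(seq, list(range(10))), seq]
        _, D = distance_matrix(_aln(rows), model="p")
        assert D[0, 1] == pytest.approx(0.10)

    def test_jc69_closed_form(self, rng):
        seq = random_seq(rng, 1000)
        rows = [seq, mutate(seq, list(range(100))), seq]
        _, D = distance_matrix(_aln(rows), model="JC69")
        assert D[0, 1] == pytest.approx(0.10732, abs=1e-5)

    def test_gap_columns_excluded_pairwise(self, rng):
        seq = random_seq(rng, 100)
        rows = [seq, "-" * 50 + seq[50:], seq]
        _, D = distance_matrix(_aln(rows), model="p")
        assert D[0, 1] == 0.0

    def test_saturated_pair_raises(self, rng):
        seq = random_seq(rng, 100)
        far = mutate(seq, list(range(100)))  # p = 1.0
        with pytest.raises(DistanceError):
            distance_matrix(_aln([seq, far, seq]), model="JC69")


class TestNJTree:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_additive_four_taxon_matrix_recovered(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) gives these pairwise path lengths
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            dtype=float,
        )
        tree = nj_tree(D, list("abcd"))
        sides = {side for _, side in bipartitions(tree)}
        assert frozenset({"c", "d"}) in sides or frozenset({"a", "b"}) in sides
        dists = tree_distances(tree)
        for (i, j), expected in {
            ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
            ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
        }.items():
            assert dists[(i, j)] == pytest.approx(expected)

    def test_matches_scikit_bio_topology(self, rng):
        # independent implementation cross-check on random distances
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        for trial in range(5):
            n = 6
            coords = rng.random((n, 4))
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    D[i, j] = np.abs(coords[i] - coords[j]).sum()
            labels = [f"t{i}" for i in range(n)]
            ours = nj_tree(D, labels)
            theirs = skbio_nj(DistanceMatrix(D, labels))
            our_sides = {side for _, side in bipartitions(ours)}
            their_sides = set()
            all_names = frozenset(labels)
            ref = min(all_names)
            for node in theirs.non_tips():
                below = frozenset(t.name for t in node.tips())
                side = below if ref not in below else all_names - below
                if 1 < len(side) < n - 1:
                    their_sides.add(side)
            assert our_sides == their_sides

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, list("abc"))

    def test_negative_branch_lengths_clamped(self):
        D = np.array(
            [[0, 0.1, 0.1, 0.4], [0.1, 0, 0.1, 0.4],
             [0.1, 0.1, 0, 0.1], [0.4, 0.4, 0.1, 0]]
        )
        tree = nj_tree(D, list("abcd"))
        for node in tree.postorder():
            assert node.length >= 0


class TestBootstrap:
    def test_identical_sequences_star_no_supports(self, rng):
        seq = random_seq(rng, 200)
        tree, supports = bootstrap_support(_aln([seq] * 4), replicates=10,
                                           seed=1)
        assert supports == {}

    def test_congruent_split_gets_full_support(self, rng):
        block = random_seq(rng, 1000)
        other = mutate(block, list(range(0, 1000, 10)))
        rows = [block, block, other, other]
        rows = [mutate(r, [i]) for i, r in enumerate(rows)]  # make leaves distinct
        tree, supports = bootstrap_support(_aln(rows), replicates=100, seed=1)
        assert supports
        assert max(supports.values()) == pytest.approx(100.0)

    def test_same_seed_reproduces_supports(self, rng):
        seq = random_seq(rng, 400)
        rows = [seq, mutate(seq, [1, 50]), mutate(seq, [100, 200, 300]),
                mutate(seq, list(range(0, 400, 21))),
                mutate(seq, list(range(5, 400, 17)))]
        _, s1 = bootstrap_support(_aln(rows), replicates=50, seed=9)
        _, s2 = bootstrap_support(_aln(rows), replicates=50, seed=9)
        assert s1 == s2

    def test_supports_invariant_under_row_permutation(self, rng):
        seq = random_seq(rng, 600)
        rows = [seq, mutate(seq, list(range(0, 600, 31))),
                mutate(seq, list(range(0, 600, 13))),
                mutate(seq, list(range(7, 600, 13))),
                mutate(seq, list(range(0, 600, 7)))]
        ids = [f"s{i}" for i in range(5)]
        _, ref = bootstrap_support(_aln(rows, ids=ids), replicates=80, seed=3)
        order = [3, 1, 4, 0, 2]
        _, perm = bootstrap_support(
            _aln([rows[i] for i in order], ids=[ids[i] for i in order]),
            replicates=80, seed=3,
        )
        assert set(ref) == set(perm)


class TestFilterBySupport:
    @pytest.mark.parametrize(
        "supports,cutoff,expected",
        [
            ([100.0, 98.0], 60.0, True),
            ([95.0, 59.0], 60.0, False),
            ([60.0], 60.0, True),  # boundary: "under 60%" is discarded
            ([59.9], 60.0, False),
            ([10.0, 20.0], 0.0, True),
        ],
    )
    def test_cutoff_rule(self, supports, cutoff, expected):
        children = [Node(name=f"l{i}") for i in range(2)]
        inner = [
            Node(support=s, children=[Node(name=f"x{i}a"), Node(name=f"x{i}b")])
            for i, s in enumerate(supports)
        ]
        tree = Node(children=children + inner)
        passed, _ = filter_by_support(tree, cutoff)
        assert passed is expected

    def test_star_tree_passes_trivially(self):
        tree = Node(children=[Node(name=c) for c in "abc"])
        passed, min_support = filter_by_support(tree)
        assert passed and min_support is None


class TestRooting:
    def _tree(self):
        return parse_newick(
            "((A:0.1,B:0.2):0.05,(C:0.3,O:0.4):0.02);",
            species_map={"A": "polyploid", "B": "parent_s",
                         "C": "parent_t", "O": "outgroup"},
        )

    def test_outgroup_becomes_basal(self):
        rooted = root_at_outgroup(self._tree())
        assert len(rooted.children) == 2
        names = sorted(
            ",".join(sorted(l.name for l in c.leaves()))
            for c in rooted.children
        )
        assert names == ["A,B,C", "O"]
        out_leaf = next(l for l in rooted.leaves() if l.name == "O")
        assert out_leaf.length == pytest.approx(0.2)

    def test_missing_outgroup_rejected(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);",
                            species_map={n: "x" for n in "ABCD"})
        with pytest.raises(ValueError, match="outgroup"):
            root_at_outgroup(tree)

    def test_rooting_preserves_bipartitions(self, rng):
        seq = random_seq(rng, 500)
        rows = [seq, mutate(seq, list(range(0, 500, 25))),
                mutate(seq, list(range(0, 500, 11))),
                mutate(seq, list(range(3, 500, 11))),
                mutate(seq, list(range(0, 500, 5)))]
        ids = ["a1", "b1", "c1", "c2", "og"]
        species = ["polyploid", "parent_s", "parent_t", "parent_t",
                   "outgroup"]
        aln = _aln(rows, ids=ids, species=species)
        labels, D = distance_matrix(aln)
        tree = nj_tree(D, labels, species=species)
        rooted = root_at_outgroup(tree)
        before = {side for _, side in bipartitions(tree)}
        after = {side for _, side in bipartitions(rooted)}
        assert before == after

    def test_patristic_distances_preserved_by_rooting(self):
        tree = self._tree()
        rooted = root_at_outgroup(tree)
        assert tree_distances(rooted) == pytest.approx(tree_distances(tree))
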