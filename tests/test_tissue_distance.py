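import numpy as np
import pytest
import skbio

from swepatlas.tissue_distance import (
    FORMULAS,
    DistanceMatrix,
    build_distance_matrix,
    count_identical_sweps,
    genes_expressed,
    neighbor_joining,
    pairwise_distance,
    read_newick,
    write_newick,
)
from .conftest import make_matrix


class TestCounts:
    def test_genes_expressed_collapses_domains(self):
        m = make_matrix(
            [
                ("g1", "limb", "muscle", "0011"),
                ("g1", "limb", "tendon", "0001"),
                ("g2", "limb", None, "1111"),
                ("g3", "somites", None, "0011"),
                ("g1", "somites", None, "0011"),
            ]
        )
        assert genes_expressed(m, "limb") == {"g1", "g2"}
        assert genes_expressed(m, "somites") == {"g1", "g3"}

    def test_unknown_structure(self, toy_matrix):
        with pytest.raises(KeyError):
            genes_expressed(toy_matrix, "notochord")

    def test_identical_swep_count_toy(self):
        m = make_matrix(
            [
                ("g1", "A", None, "0011"),
                ("g1", "B", None, "0011"),
                ("g2", "A", None, "0011"),
                ("g2", "B", None, "0111"),
                ("g3", "A", None, "1111"),
            ]
        )
        assert count_identical_sweps(m, "A", "B") == 1  # only g1 matches
        assert count_identical_sweps(m, "A", "A") == len(genes_expressed(m, "A"))

    def test_multi_domain_union_is_compared(self):
        # g1 in A covers 0011 | 0110 = 0111, equal to its single-domain SWEP in B
        m = make_matrix(
            [
                ("g1", "A", "d1", "0011"),
                ("g1", "A", "d2", "0110"),
                ("g1", "B", None, "0111"),
            ]
        )
        assert count_identical_sweps(m, "A", "B") == 1


class TestPairwiseDistance:
    def test_identical_structures_have_zero_distance(self):
        for f in FORMULAS:
            assert pairwise_distance(6, 6, 6, f) == pytest.approx(0.0)

    def test_no_shared_identical_genes_gives_one(self):
        for f in FORMULAS:
            assert pairwise_distance(5, 9, 0, f) == pytest.approx(1.0)

    def test_dice_arithmetic(self):
        assert pairwise_distance(10, 6, 4, "dice") == pytest.approx(0.5)  # 1 - 8/16

    @pytest.mark.parametrize("formula", sorted(FORMULAS))
    def test_constraints_hold_on_a_grid(self, formula):
        # acceptance runs the full 1..50 sweep; here a fast 1..12 slice
        for na in range(1, 13):
            for nb in range(1, 13):
                for c in range(0, min(na, nb) + 1):
                    d = pairwise_distance(na, nb, c, formula)
                    assert 0.0 <= d <= 1.0
                    assert (d == 0.0) == (na == nb == c)
                    assert (d == 1.0) == (c == 0)

    def test_empty_structure_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            pairwise_distance(0, 5, 0)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pairwise_distance(3, 4, 4)
        with pytest.raises(KeyError):
            pairwise_distance(3, 4, 2, formula="cosine")


class TestDistanceMatrix:
    def test_toy_matrix_matches_hand_computation(self, toy_matrix):
        # Hand counts: N(liver)=5, N(gut)=3, N(heart)=2, N(eye)=3;
        # C(liver,gut)=1 (g01), C(liver,heart)=1 (g06), C(liver,eye)=1 (g09),
        # all other pairs share nothing identical.
        dm = build_distance_matrix(toy_matrix, ["liver", "gut", "heart", "eye"])
        assert dm["liver", "gut"] == pytest.approx(1 - 2 / 8)
        assert dm["liver", "heart"] == pytest.approx(1 - 2 / 7)
        assert dm["liver", "eye"] == pytest.approx(1 - 2 / 8)
        assert dm["gut", "heart"] == 1.0
        assert dm["gut", "eye"] == 1.0
        assert dm["heart", "eye"] == 1.0
        assert np.allclose(np.diag(dm.values), 0)

    def test_identical_and_disjoint_structures(self):
        m = make_matrix(
            [
                ("g1", "A", None, "0011"), ("g2", "A", None, "1111"),
                ("g1", "B", None, "0011"), ("g2", "B", None, "1111"),
                ("g3", "C", None, "0111"),
            ]
        )
        dm = build_distance_matrix(m)
        assert dm["A", "B"] == 0.0
        assert dm["A", "C"] == 1.0

    def test_empty_structure_listed_raises(self, toy_matrix):
        with pytest.raises((ValueError, KeyError)):
            build_distance_matrix(toy_matrix, ["liver", "notochord"])

    def test_symmetry_and_bounds_on_random_matrices(self):
        rng = np.random.default_rng(7)
        structs = [f"S{i}" for i in range(5)]
        entries = []
        for g in range(60):
            for s in structs:
                if rng.random() < 0.4:
                    lo = int(rng.integers(4))
                    hi = int(rng.integers(lo, 4))
                    entries.append(
                        (f"g{g}", s, None,
                         "".join("1" if lo <= i <= hi else "0" for i in range(4)))
                    )
        m = make_matrix(sorted(set(entries)))
        for f in FORMULAS:
            dm = build_distance_matrix(m, formula=f)
            assert np.allclose(dm.values, dm.values.T)
            assert (dm.values >= 0).all() and (dm.values <= 1).all()

    def test_tsv_round_trip(self, toy_matrix):
        dm = build_distance_matrix(toy_matrix)
        again = DistanceMatrix.from_tsv(dm.to_tsv())
        assert again.structures == dm.structures
        assert np.allclose(again.values, dm.values)

    def test_phylip_square_format(self, toy_matrix):
        text = build_distance_matrix(toy_matrix).to_phylip()
        lines = text.strip().split("\n")
        assert lines[0] == "4"
        assert len(lines) == 5


def _random_additive(rng, n):
    """A random unrooted binary tree on n leaves and its path-length matrix."""
    labels = [f"L{i}" for i in range(n)]
    tree = skbio.TreeNode.read(iter([_random_topology(rng, labels) + ";"]))
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(0.1, 2.0))
    tip = {t.name: t for t in tree.tips()}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tip[labels[i]].distance(tip[labels[j]])
    return labels, tree, DistanceMatrix(labels, d)


def _random_topology(rng, labels):
    if len(labels) == 1:
        return labels[0]
    if len(labels) == 2:
        return f"({labels[0]},{labels[1]})"
    k = int(rng.integers(1, len(labels) - 1))
    idx = rng.permutation(len(labels))
    left = [labels[i] for i in idx[:k]]
    right = [labels[i] for i in idx[k:]]
    return f"({_random_topology(rng, left)},{_random_topology(rng, right)})"


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})
        assert write_newick(tree, 3) == "(A:1,B:2,C:3);"

    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_recovers_additive_trees_exactly(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            labels, true_tree, dm = _random_additive(rng, n)
            est = neighbor_joining(dm)
            assert est.compare_rfd(true_tree) == 0.0
            # branch lengths: compare all leaf-to-leaf path lengths
            tip = {t.name: t for t in est.tips()}
            for i in range(n):
                for j in range(i + 1, n):
                    assert tip[labels[i]].distance(tip[labels[j]]) == pytest.approx(
                        dm.values[i, j], abs=1e-9
                    )

    def test_matches_reference_nj_topology(self):
        # independent oracle: scikit-bio's NJ on a generic (tie-free) matrix
        rng = np.random.default_rng(42)
        n = 7
        labels = [f"S{i}" for i in range(n)]
        a = rng.uniform(0.2, 1.0, size=(n, n))
        d = np.triu(a, 1) + np.triu(a, 1).T
        dm = DistanceMatrix(labels, d)
        ours = neighbor_joining(dm, clamp_negative=False)
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        assert ours.compare_rfd(ref) == 0.0

    def test_all_zero_distances_star_is_deterministic(self):
        dm = DistanceMatrix(tuple("ABCDE"), np.zeros((5, 5)))
        t1 = write_newick(neighbor_joining(dm))
        t2 = write_newick(neighbor_joining(dm))
        assert t1 == t2
        assert all(t.length == 0 for t in neighbor_joining(dm).tips())

    def test_two_leaves_single_edge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 2.0], [2.0, 0]]))
        assert write_newick(neighbor_joining(dm)) == "(A:1,B:1);"

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A",), np.zeros((1, 1))))

    def test_negative_branch_clamping_toggle(self):
        # non-additive matrix known to yield one negative internal branch
        d = np.array(
            [[0, 0.31, 0.09, 0.07], [0.31, 0, 0.63, 0.74],
             [0.09, 0.63, 0, 0.05], [0.07, 0.74, 0.05, 0]]
        )
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        clamped = neighbor_joining(dm, clamp_negative=True)
        assert min(node.length for node in clamped.traverse(include_self=False)) >= 0
        raw = neighbor_joining(dm, clamp_negative=False)
        assert min(node.length for node in raw.traverse(include_self=False)) < 0

    def test_determinism_byte_identical(self, toy_matrix):
        dm = build_distance_matrix(toy_matrix)
        assert write_newick(neighbor_joining(dm)) == write_newick(neighbor_joining(dm))


class TestNewick:
    def test_round_trip_is_isomorphic(self, toy_matrix):
        tree = neighbor_joining(build_distance_matrix(toy_matrix))
        text = write_newick(tree)
        again = read_newick(text)
        assert again.compare_rfd(tree) == 0.0
        assert write_newick(again) == text
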