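"""Trees, phylogenetic diversity, UniFrac, ordination, PERMANOVA."""

import io
import math

import numpy as np
import pytest

from ighrep import (
    DistanceMatrix,
    PhyloTree,
    build_nj_tree,
    faith_pd,
    pairwise_cdr3_distance,
    pcoa,
    permanova,
    shannon_index,
    weighted_unifrac,
)
from conftest import make_sample
from _oracles import (
    brute_edit_distance,
    brute_faith_pd,
    brute_weighted_unifrac,
    random_tree,
)


# --- CDR3 pairwise distance ------------------------------------------------

class TestCdr3Distance:
    def test_identity_and_single_gap(self):
        dm = pairwise_cdr3_distance(["CARDW", "CARW"])
        assert dm[("CARDW", "CARDW")] == 0.0
        assert abs(dm[("CARW", "CARDW")] - 1 / 5) < 1e-12

    def test_matches_exhaustive_recursion(self):
        rng = np.random.default_rng(42)
        alphabet = "ACDW"
        seqs = list({
            "".join(rng.choice(list(alphabet), size=rng.integers(2, 9)))
            for _ in range(12)
        })
        dm = pairwise_cdr3_distance(seqs)
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                expected = brute_edit_distance(a, b) / max(len(a), len(b))
                assert abs(dm.values[i, j] - expected) < 1e-12

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            pairwise_cdr3_distance(["CAXW", "CARW"])


# --- neighbor joining ------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxon_pendant_lengths(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        tree = build_nj_tree(dm)
        d = tree.leaf_distances()
        assert abs(d[("A", "B")] - 2) < 1e-12
        assert abs(d[("A", "C")] - 3) < 1e-12
        assert abs(d[("B", "C")] - 3) < 1e-12

    def test_additive_four_taxon_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)); additive distances
        vals = np.array(
            [
                [0, 3, 6, 4],
                [3, 0, 7, 5],
                [6, 7, 0, 4],
                [4, 5, 4, 0],
            ],
            float,
        )
        dm = DistanceMatrix(("A", "B", "C", "D"), vals)
        tree = build_nj_tree(dm)
        d = tree.leaf_distances()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if a != b:
                    assert abs(d[(a, b)] - vals[i, j]) < 1e-9

    def test_ultrametric_matrix_additive_paths(self):
        vals = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            float,
        )
        dm = DistanceMatrix(("A", "B", "C", "D"), vals)
        tree = build_nj_tree(dm)
        d = tree.leaf_distances()
        # single-linkage topology: A-B closest, then C, then D
        assert d[("A", "B")] < d[("A", "C")] < d[("A", "D")]

    def test_fewer_than_three_labels_rejected(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="star"):
            build_nj_tree(dm)

    def test_branch_lengths_non_negative_on_noisy_input(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        vals = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(tuple(f"L{i}" for i in range(8)), vals)
        tree = build_nj_tree(dm)
        assert all(n.length >= 0 for n in tree.preorder())


# --- newick round trip -----------------------------------------------------

def test_newick_round_trip_preserves_topology_and_lengths():
    rng = np.random.default_rng(9)
    for _ in range(10):
        tree = random_tree(rng, int(rng.integers(3, 12)))
        back = PhyloTree.from_newick(tree.to_newick())
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)
        d1, d2 = tree.leaf_distances(), back.leaf_distances()
        for k in d1:
            assert abs(d1[k] - d2[k]) < 1e-9


# --- alpha diversity -------------------------------------------------------

class TestShannon:
    def test_single_clonotype_zero(self):
        s = make_sample("S", "nontreated", "IGHG", [("CARW", "V", "J", 5)])
        assert shannon_index(s) == 0.0

    def test_uniform_is_log_n(self):
        rows = [(f"C{'A' * i}W", "V", "J", 7) for i in range(16)]
        s = make_sample("S", "nontreated", "IGHG", rows)
        assert abs(shannon_index(s) - math.log(16)) < 1e-12

    def test_closed_form_value(self):
        s = make_sample("S", "nontreated", "IGHG",
                        [("CAW", "V", "J", 2), ("CCW", "V", "J", 1), ("CDW", "V", "J", 1)])
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert abs(shannon_index(s) - expected) < 1e-12
        assert abs(expected - 1.0397207708399179) < 1e-12

    def test_uniform_maximizes(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=20)
        rows = [(f"C{'A' * i}W", "V", "J", int(c)) for i, c in enumerate(counts)]
        s = make_sample("S", "nontreated", "IGHG", rows)
        assert shannon_index(s) <= math.log(20) + 1e-12


class TestFaithPD:
    def test_toy_tree_values(self, toy_tree):
        assert faith_pd(toy_tree, {"A", "C"}) == pytest.approx(4.5, abs=1e-12)
        assert faith_pd(toy_tree, {"A", "B", "C"}) == pytest.approx(6.5, abs=1e-12)

    def test_unknown_leaf_named(self, toy_tree):
        with pytest.raises(KeyError, match="Z"):
            faith_pd(toy_tree, {"A", "Z"})

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(3, 17)))
            names = tree.leaf_names
            k = int(rng.integers(1, len(names) + 1))
            observed = set(rng.choice(names, size=k, replace=False))
            assert faith_pd(tree, observed) == pytest.approx(
                brute_faith_pd(tree, observed), abs=1e-9
            )

    def test_monotone_in_observed_set(self):
        rng = np.random.default_rng(8)
        tree = random_tree(rng, 10)
        names = tree.leaf_names
        observed = {names[0]}
        pd_prev = faith_pd(tree, observed)
        for name in names[1:]:
            observed.add(name)
            pd_next = faith_pd(tree, observed)
            assert pd_next >= pd_prev - 1e-12
            pd_prev = pd_next


class TestWeightedUnifrac:
    def test_identical_abundances_zero(self, toy_tree):
        a = {"A": 0.2, "B": 0.5, "C": 0.3}
        assert weighted_unifrac(toy_tree, a, dict(a)) == 0.0

    def test_disjoint_mass_is_one(self, toy_tree):
        assert weighted_unifrac(toy_tree, {"A": 1.0}, {"C": 1.0}) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(3, 17)))
            names = tree.leaf_names
            a = dict(zip(names, rng.dirichlet(np.ones(len(names)))))
            b = dict(zip(names, rng.dirichlet(np.ones(len(names)))))
            assert weighted_unifrac(tree, a, b) == pytest.approx(
                brute_weighted_unifrac(tree, a, b), abs=1e-9
            )

    def test_symmetry_and_empirical_triangle(self):
        rng = np.random.default_rng(19)
        tree = random_tree(rng, 9)
        names = tree.leaf_names
        vecs = [dict(zip(names, rng.dirichlet(np.ones(len(names))))) for _ in range(3)]
        d01 = weighted_unifrac(tree, vecs[0], vecs[1])
        d10 = weighted_unifrac(tree, vecs[1], vecs[0])
        assert d01 == pytest.approx(d10, abs=1e-12)
        d02 = weighted_unifrac(tree, vecs[0], vecs[2])
        d12 = weighted_unifrac(tree, vecs[1], vecs[2])
        assert d02 <= d01 + d12 + 1e-9

    def test_bad_abundance_sum_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="sums to"):
            weighted_unifrac(toy_tree, {"A": 0.5}, {"C": 1.0})

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity.beta import weighted_unifrac as sk_wuf

        rng = np.random.default_rng(23)
        for _ in range(5):
            tree = random_tree(rng, 8)
            names = tree.leaf_names
            ca = rng.integers(0, 50, size=len(names)) + 1
            cb = rng.integers(0, 50, size=len(names)) + 1
            a = dict(zip(names, ca / ca.sum()))
            b = dict(zip(names, cb / cb.sum()))
            sk_tree = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
            expected = sk_wuf(ca, cb, taxa=names, tree=sk_tree, normalized=True)
            assert weighted_unifrac(tree, a, b) == pytest.approx(expected, abs=1e-9)


# --- PCoA ------------------------------------------------------------------

class TestPcoa:
    def test_collinear_points_single_axis(self):
        vals = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        dm = DistanceMatrix(("a", "b", "c"), vals)
        res = pcoa(dm, n_axes=1)
        assert (res.eigenvalues > 1e-9).sum() == 1
        coords = res.coordinates[:, 0]
        gaps = np.abs(np.diff(np.sort(coords)))
        assert np.allclose(gaps, [1, 1], atol=1e-9)

    def test_identical_points_all_zero_eigenvalues(self):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="truncating"):
            res = pcoa(dm, n_axes=1)
        assert np.allclose(res.eigenvalues, 0, atol=1e-12)

    def test_euclidean_embedding_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        vals = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(tuple(f"p{i}" for i in range(7)), vals)
        res = pcoa(dm, n_axes=6)
        coords = res.coordinates
        rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(rec, vals, atol=1e-9)


# --- PERMANOVA -------------------------------------------------------------

def worked_example_matrix():
    vals = np.array(
        [[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], float
    )
    return DistanceMatrix(("s1", "s2", "s3", "s4"), vals)


class TestPermanova:
    GROUPING = {"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"}

    def test_worked_example_f_and_exhaustive_p(self):
        res = permanova(worked_example_matrix(), self.GROUPING, n_permutations=99999)
        assert res.pseudo_f == pytest.approx(7.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert res.method == "exhaustive"

    def test_f_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(31)
        vals = np.abs(rng.normal(size=(8, 8)))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        ids = tuple(f"s{i}" for i in range(8))
        grouping = {i: ("a" if k < 4 else "b") for k, i in enumerate(ids)}
        mine = permanova(DistanceMatrix(ids, vals), grouping, n_permutations=99)
        theirs = sk_permanova(SkDM(vals, ids=list(ids)),
                              grouping=[grouping[i] for i in ids], permutations=9)
        assert mine.pseudo_f == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_invariant_to_group_label_names(self):
        dm = worked_example_matrix()
        res1 = permanova(dm, self.GROUPING, 999)
        res2 = permanova(dm, {k: v.replace("g", "zzz") for k, v in self.GROUPING.items()}, 999)
        assert res1.pseudo_f == res2.pseudo_f
        assert res1.p_value == res2.p_value

    def test_sampled_path_seed_determinism(self):
        rng = np.random.default_rng(5)
        vals = np.abs(rng.normal(size=(12, 12)))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        ids = tuple(f"s{i}" for i in range(12))
        grouping = {i: ("a" if k % 2 else "b") for k, i in enumerate(ids)}
        dm = DistanceMatrix(ids, vals)
        r1 = permanova(dm, grouping, n_permutations=500, seed=42)
        r2 = permanova(dm, grouping, n_permutations=500, seed=42)
        assert r1.method == "sampled"
        assert r1.p_value == r2.p_value

    def test_singleton_group_rejected(self):
        dm = worked_example_matrix()
        with pytest.raises(ValueError, match="at least two samples"):
            permanova(dm, {"s1": "g1", "s2": "g1", "s3": "g1", "s4": "g2"}, 99)

    def test_all_zero_distances_rejected(self):
        dm = DistanceMatrix(("a", "b", "c", "d"), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="zero"):
            permanova(dm, self.GROUPING | {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, 99)
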