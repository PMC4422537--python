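"""Distance matrices and UPGMA against hand calculations and brute force."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as sph
from scipy.spatial.distance import squareform

from germcore.distance import (
    DistanceMatrix,
    cut_tree,
    group_dissimilarity,
    jaccard_distance,
    modified_rogers_distance,
    standardized_euclidean,
    upgma,
)

from conftest import make_panel


def brute_force_upgma(labels, D):
    """Reference UPGMA: cluster averages recomputed from the original
    matrix at every step (independent of the incremental update path)."""
    clusters = [[i] for i in range(len(labels))]
    ids = list(range(len(labels)))
    next_id = len(labels)
    Z = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([D[i][j] for i in clusters[a] for j in clusters[b]])
                key_lab = tuple(
                    sorted(
                        (
                            min(labels[i] for i in clusters[a]),
                            min(labels[i] for i in clusters[b]),
                        )
                    )
                )
                if best is None or avg < best[0] - 1e-12 or (
                    abs(avg - best[0]) <= 1e-12 and key_lab < best[1]
                ):
                    best = (avg, key_lab, a, b)
        avg, _, a, b = best
        Z.append([min(ids[a], ids[b]), max(ids[a], ids[b]), avg,
                  len(clusters[a]) + len(clusters[b])])
        clusters[a] = clusters[a] + clusters[b]
        ids[a] = next_id
        next_id += 1
        del clusters[b], ids[b]
    return np.array(Z)


class TestStandardizedEuclidean:
    def test_identical_vectors_distance_zero(self):
        panel = make_panel({"L": ["A", "B"]}, traits={"T1": [2.0, 2.0], "T2": [5.0, 5.0]})
        assert standardized_euclidean(panel).values[0, 1] == 0.0

    def test_two_point_hand_calculation(self):
        panel = make_panel({"L": ["A", "B"]}, traits={"T1": [0.0, 2.0]})
        # z-scores with n-1 SD: +-1/sqrt(2), distance = sqrt(2)
        assert standardized_euclidean(panel).values[0, 1] == pytest.approx(np.sqrt(2))

    def test_permutation_equivariance(self, sim_panel):
        panel, _ = sim_panel
        idx = list(range(20))
        perm = idx[::-1]
        d1 = standardized_euclidean(panel, subset=idx).values
        d2 = standardized_euclidean(panel, subset=perm).values
        np.testing.assert_allclose(d1, d2[::-1, ::-1], atol=1e-9)

    def test_pair_with_no_shared_descriptor_is_an_error(self):
        panel = make_panel(
            {"L": ["A", "B"]},
            traits={"T1": [1.0, np.nan], "T2": [np.nan, 2.0]},
        )
        with pytest.raises(ValueError, match="A1"):
            standardized_euclidean(panel)


class TestJaccard:
    def test_identical_profiles_zero(self):
        panel = make_panel({"L1": ["a", "a"], "L2": ["x", "x"]})
        assert jaccard_distance(panel).values[0, 1] == 0.0

    def test_disjoint_profiles_one(self):
        panel = make_panel({"L1": ["a", "b"], "L2": ["x", "y"]})
        assert jaccard_distance(panel).values[0, 1] == 1.0

    def test_direct_count_oracle(self):
        # a=2 shared, b=1, c=1 mismatched bands -> s = 0.5
        panel = make_panel(
            {"L1": ["a", "a"], "L2": ["x", "x"], "L3": ["p", "q"]}
        )
        assert jaccard_distance(panel).values[0, 1] == pytest.approx(0.5)

    def test_invariant_to_band_absent_in_both(self):
        p1 = make_panel({"L1": ["a", "a", "b"], "L2": ["x", "y", "y"]})
        d1 = jaccard_distance(p1, subset=[0, 1]).values[0, 1]
        # third accession introduces band "b"; pair (0,1) unaffected
        d_full = jaccard_distance(p1).values[0, 1]
        assert d1 == pytest.approx(d_full)

    def test_missing_locus_excluded_pairwise(self):
        panel = make_panel({"L1": ["a", None], "L2": ["x", "x"]})
        assert jaccard_distance(panel).values[0, 1] == 0.0


class TestModifiedRogers:
    def test_identical_zero_and_full_difference_one(self):
        same = make_panel({"L1": ["a", "a"], "L2": ["x", "x"]})
        assert modified_rogers_distance(same).values[0, 1] == 0.0
        diff = make_panel({"L1": ["a", "b"], "L2": ["x", "y"], "L3": ["p", "q"]})
        assert modified_rogers_distance(diff).values[0, 1] == pytest.approx(1.0)

    def test_half_difference_formula(self):
        panel = make_panel({"L1": ["a", "b"], "L2": ["x", "x"]})
        assert modified_rogers_distance(panel).values[0, 1] == pytest.approx(np.sqrt(0.5))

    def test_triangle_inequality_on_random_triples(self, sim_panel):
        panel, _ = sim_panel
        rng = np.random.default_rng(7)
        d_mr = modified_rogers_distance(panel).values
        d_eu = standardized_euclidean(panel).values
        n = len(panel)
        for _ in range(500):
            i, j, k = rng.choice(n, size=3, replace=False)
            for D in (d_mr, d_eu):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestUPGMA:
    def test_two_leaves(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = upgma(d)
        assert tree.linkage[0, 2] == 1.0

    def test_three_leaf_hand_execution(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = upgma(d)
        np.testing.assert_allclose(tree.linkage[:, 2], [2.0, 4.0])
        assert cut_tree(tree, 3.0) == {"A": 0, "B": 0, "C": 1}
        assert cut_tree(tree, 5.0) == {"A": 0, "B": 0, "C": 0}
        assert len(set(cut_tree(tree, 0.0).values())) == 3

    def test_ultrametric_input_is_fixed_point(self):
        # cophenetic matrix of any UPGMA tree is ultrametric: rerunning
        # UPGMA on it must reproduce it exactly
        rng = np.random.default_rng(3)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(6)]
        tree = upgma(DistanceMatrix(labels, m))
        coph = tree.cophenetic()
        tree2 = upgma(coph)
        np.testing.assert_allclose(tree2.cophenetic().values, coph.values, atol=1e-9)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_brute_force_reference(self, n):
        rng = np.random.default_rng(n)
        for rep in range(10):
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, m))
            ref = brute_force_upgma(labels, m)
            np.testing.assert_allclose(tree.linkage, ref, atol=1e-9)

    def test_agrees_with_scipy_average_linkage(self):
        rng = np.random.default_rng(17)
        m = rng.random((15, 15))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = upgma(DistanceMatrix([f"t{i}" for i in range(15)], m))
        Z = sph.average(squareform(m))
        # merge heights and cophenetic structure agree (node ids may differ)
        np.testing.assert_allclose(np.sort(tree.linkage[:, 2]), np.sort(Z[:, 2]), atol=1e-9)
        np.testing.assert_allclose(
            tree.cophenetic().values, squareform(sph.cophenet(Z)), atol=1e-9
        )

    def test_nan_rejected_at_matrix_construction(self):
        m = np.array([[0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], m)


class TestGroupDissimilarity:
    def test_duplicated_group_zero(self):
        panel = make_panel({"L1": ["a", "b", "a", "b"]})
        grouping = {"A1": "g1", "A2": "g1", "A3": "g2", "A4": "g2"}
        d = group_dissimilarity(panel, grouping)
        assert d.values[0, 1] == 0.0

    def test_opposite_monomorphic_groups_one(self):
        panel = make_panel({"L1": ["a", "a", "b", "b"], "L2": ["x", "x", "y", "y"]})
        grouping = {"A1": "g1", "A2": "g1", "A3": "g2", "A4": "g2"}
        assert group_dissimilarity(panel, grouping).values[0, 1] == pytest.approx(1.0)

    def test_formula_evaluation_oracle(self):
        # freqs {1,0} vs {0.5,0.5} at one locus -> sqrt(0.5/2) = 0.5
        panel = make_panel({"L1": ["a", "a", "a", "b"]})
        grouping = {"A1": "g1", "A2": "g1", "A3": "g2", "A4": "g2"}
        assert group_dissimilarity(panel, grouping).values[0, 1] == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        panel = make_panel({"L1": ["a", "b"]})
        with pytest.raises(ValueError):
            group_dissimilarity(panel, {"A1": "g1"})
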