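"""Collection-comparison statistics against closed-form and library oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from germcore.distance import DistanceMatrix, modified_rogers_distance, standardized_euclidean
from germcore.model import Selection
from germcore.simulate import SimulationConfig, simulate_panel
from germcore.validation import (
    compare_collections,
    compare_correlations,
    equality_test,
    homogeneity_test,
    mantel_test,
    qq_kl,
)


class TestEqualityTest:
    def test_identical_samples_not_rejected(self):
        x = np.arange(50.0)
        res = equality_test(x, x)
        assert res.p_value > 0.9

    def test_maximal_separation(self):
        # oracle frozen from scipy.stats.median_test(ties="below",
        # correction=False): chi2 = 100, p ~ 1.5e-23
        res = equality_test(np.arange(1.0, 51.0), np.arange(51.0, 101.0))
        assert res.statistic == pytest.approx(100.0)
        assert res.p_value < 1e-10

    def test_all_equal_degenerate(self):
        res = equality_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p_value == 1.0

    def test_type_one_error_near_nominal(self):
        """Same-distribution draws rejected at ~5% (alpha = 0.05)."""
        rng = np.random.default_rng(42)
        rejections = sum(
            equality_test(rng.normal(size=200), rng.normal(size=200)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08


class TestHomogeneityTest:
    def test_identical_samples(self):
        x = np.linspace(0, 10, 100)
        res = homogeneity_test(x, x, n_classes=10)
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_disjoint_classes_rejected(self):
        res = homogeneity_test(
            np.random.default_rng(1).uniform(0, 1, 200),
            np.random.default_rng(2).uniform(9, 10, 200),
            n_classes=10,
        )
        assert res.p_value < 1e-10

    def test_contingency_closed_form_oracle(self):
        # 2x3 table {{10,20,30},{30,20,10}}: expected all 20 ->
        # chi2 = 4 * (10-20)^2/20 = 20, p = chi2.sf(20, 2) ~ 4.54e-5
        x = np.repeat([0.5, 1.5, 2.5], [10, 20, 30])
        y = np.repeat([0.5, 1.5, 2.5], [30, 20, 10])
        res = homogeneity_test(x, y, n_classes=3, bin_edges=np.array([0.0, 1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value == pytest.approx(sps.chi2.sf(20.0, 2), rel=1e-9)
        assert res.df == 2

    def test_sparse_classes_pooled(self):
        x = np.concatenate([np.zeros(50), [10.0]])
        y = np.zeros(50)
        res = homogeneity_test(x, y, n_classes=10)
        assert 0 <= res.p_value <= 1

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        edges = np.linspace(-3.5, 3.5, 11)
        rejections = sum(
            homogeneity_test(
                rng.normal(size=300), rng.normal(size=300), 10, bin_edges=edges
            ).p_value
            < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08


class TestQQKL:
    def test_identical_samples_on_diagonal(self):
        x = np.random.default_rng(0).normal(size=500)
        res = qq_kl(x, x)
        np.testing.assert_allclose(res.quantiles_x, res.quantiles_y)
        assert res.kl == 0.0

    def test_smoothed_kl_oracle(self):
        # construct samples whose 199 quantiles fall 150/49 vs 49/150 into
        # two bins, then verify against the add-one-smoothed formula
        x = np.concatenate([np.zeros(151), np.ones(50)])
        y = np.concatenate([np.zeros(50), np.ones(151)])
        res = qq_kl(x, y, n_bins=2)
        cx = np.histogram(res.quantiles_x, bins=np.linspace(0, 1, 3))[0]
        cy = np.histogram(res.quantiles_y, bins=np.linspace(0, 1, 3))[0]
        p = (cx + 1) / (cx.sum() + 2)
        q = (cy + 1) / (cy.sum() + 2)
        assert res.kl == pytest.approx(float(np.sum(p * np.log(p / q))))
        assert res.kl > 0

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=100)
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=100)
            assert qq_kl(x, y).kl >= 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = rng.normal(1.0, 2.0, size=300)
        base = qq_kl(x, y).kl
        assert qq_kl(3.0 * x - 7.0, 3.0 * y - 7.0).kl == pytest.approx(base, rel=1e-9)

    def test_constant_samples_zero(self):
        res = qq_kl(np.full(50, 3.0), np.full(60, 3.0))
        assert res.kl == 0.0


def _random_distance(n, rng):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix([f"t{i}" for i in range(n)], m)


class TestMantel:
    def test_self_comparison(self):
        d = _random_distance(8, np.random.default_rng(1))
        res = mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_matches_exact_enumeration_on_4x4(self):
        from itertools import permutations

        rng = np.random.default_rng(2)
        d1 = _random_distance(4, rng)
        d2 = _random_distance(4, rng)
        iu = np.triu_indices(4, 1)
        a = d1.values[iu]
        r_obs = np.corrcoef(a, d2.values[iu])[0, 1]
        count = sum(
            np.corrcoef(a, d2.values[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12
            for p in permutations(range(4))
        )
        exact_p = count / 24  # r_obs is reached by the identity permutation
        res = mantel_test(d1, d2, n_perm=9999, seed=3)
        assert res.r == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(exact_p, abs=0.03)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(4)
        d1 = _random_distance(12, rng)
        d2 = _random_distance(12, rng)
        r_sk, p_sk, _ = sk_mantel(
            SkDM(d1.values, d1.labels), SkDM(d2.values, d2.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        res = mantel_test(d1, d2, n_perm=999, seed=8)
        assert res.r == pytest.approx(float(r_sk), abs=1e-9)
        assert res.p_value == pytest.approx(float(p_sk), abs=0.05)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        d1 = _random_distance(5, rng)
        d2 = _random_distance(5, rng)
        d2.labels[0] = "other"
        with pytest.raises(ValueError):
            mantel_test(d1, d2)

    def test_permutation_p_never_zero(self):
        panel, _ = simulate_panel(SimulationConfig(n_accessions=30, seed=9))
        d1 = standardized_euclidean(panel)
        d2 = modified_rogers_distance(panel)
        res = mantel_test(d1, d2, n_perm=99, seed=1)
        assert res.p_value >= 1 / 100


class TestCompareCorrelations:
    def test_identical_subsets_give_unit_p(self, sim_panel):
        panel, _ = sim_panel
        idx = list(range(50))
        table = compare_correlations(panel, idx, idx)
        assert (table["z"].abs() < 1e-12).all()
        assert np.allclose(table["p_value"], 1.0)

    def test_fisher_z_closed_form(self, sim_panel):
        """Reported z must equal the closed form recomputed from the
        reported correlations and sizes; e.g. r=0.5 vs 0 at n=103 each
        gives z = 0.5493/sqrt(2/100) = 3.884, p ~ 1e-4."""
        z = (np.arctanh(0.5) - 0.0) / np.sqrt(2 / 100)
        assert z == pytest.approx(3.8840, abs=1e-3)
        assert 2 * sps.norm.sf(z) == pytest.approx(1.03e-4, rel=0.05)
        panel, _ = sim_panel
        table = compare_correlations(panel, list(range(60)), list(range(60, 120)))
        for _, row in table.iterrows():
            expected = (np.arctanh(row.r_a) - np.arctanh(row.r_b)) / np.sqrt(
                1 / (row.n_a - 3) + 1 / (row.n_b - 3)
            )
            assert row.z == pytest.approx(expected, abs=1e-9)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(500):
            r_a = np.corrcoef(rng.normal(size=(2, 100)))[0, 1]
            r_b = np.corrcoef(rng.normal(size=(2, 100)))[0, 1]
            z = (np.arctanh(r_a) - np.arctanh(r_b)) / np.sqrt(2 / 97)
            hits += 2 * sps.norm.sf(abs(z)) < 0.05
        assert 0.02 <= hits / 500 <= 0.08


class TestCompareCollections:
    def test_whole_panel_subset_is_null(self, sim_panel):
        panel, _ = sim_panel
        report = compare_collections(panel, list(range(len(panel))), n_perm=99)
        assert report.max_relative_mean_difference == pytest.approx(0.0, abs=1e-12)
        assert (report.per_descriptor["qq_kl"] == 0.0).all()
        assert np.allclose(report.per_descriptor["homogeneity_p"], 1.0)

    def test_report_covers_all_descriptors(self, sim_panel):
        panel, _ = sim_panel
        sel = Selection(panel, list(range(0, len(panel), 4)), method="sub")
        report = compare_collections(panel, sel, n_perm=99)
        assert list(report.per_descriptor.index) == panel.descriptor_codes
        for col in (
            "mean_ref", "mean_subset", "rel_mean_diff_pct", "var_ref",
            "var_subset", "equality_p", "homogeneity_p", "H_prime_ref",
            "H_prime_subset", "qq_kl",
        ):
            assert report.per_descriptor[col].notna().all(), col
        assert report.mantel is not None
        assert 1 / 100 <= report.mantel.p_value <= 1.0
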