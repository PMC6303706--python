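"""KDE construction, the ISE two-sample test, FDR, and contours."""

import numpy as np
import pytest

from platemorph.geometry import StandardizedCloud
from platemorph.spatial import (
    BandwidthMatrix,
    evaluate_kde,
    fdr_adjust,
    ise_statistic,
    kde_two_sample_test,
    pairwise_population_comparison,
    percentile_contours,
    pool_population,
    select_bandwidth,
)

I2 = BandwidthMatrix(np.eye(2))


def _rot(a):
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


class TestPoolPopulation:
    def test_concatenation(self, rng):
        a = StandardizedCloud(np.eye(3, 2), rng.normal(size=(28, 2)), "f1")
        b = StandardizedCloud(np.eye(3, 2), rng.normal(size=(30, 2)), "f2")
        pts, prov = pool_population([a, b])
        assert len(pts) == 58
        assert set(prov) == {"f1", "f2"}
        assert np.sum(prov == "f1") == 28

    def test_single_cloud_identity(self, rng):
        pts0 = rng.normal(size=(12, 2))
        pts, _ = pool_population([pts0])
        assert np.array_equal(pts, pts0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_population([])


class TestSelectBandwidth:
    def test_normal_scale_closed_form(self, rng):
        X = rng.standard_normal((1000, 2))
        H = select_bandwidth(X).H
        expected = 1000 ** (-1.0 / 3.0) * np.cov(X.T)
        assert np.allclose(H, expected, rtol=1e-12)
        # within sampling error of the population version n^(-1/3) I
        target = 1000 ** (-1.0 / 3.0)
        assert np.allclose(np.diag(H), target, rtol=0.15)
        assert abs(H[0, 1]) < 0.15 * target

    def test_rotation_equivariance(self, rng):
        X = rng.standard_normal((200, 2)) * [2.0, 0.5]
        R = _rot(np.pi / 4)
        H1 = select_bandwidth(X @ R.T).H
        H2 = R @ select_bandwidth(X).H @ R.T
        assert np.allclose(H1, H2, atol=1e-9)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError):
            select_bandwidth(pts)

    def test_plugin_is_spd_and_reasonable(self, rng):
        X = rng.standard_normal((400, 2))
        H = select_bandwidth(X, "plugin").H
        eig = np.linalg.eigvalsh(H)
        assert np.all(eig > 0)
        ratio = eig.mean() / np.linalg.eigvalsh(select_bandwidth(X).H).mean()
        assert 0.3 < ratio < 3.0  # same order as the normal-scale choice


class TestEvaluateKde:
    def test_single_point_closed_form(self):
        model = evaluate_kde(np.zeros((1, 2)), I2, grid_n=201)
        i = np.argmin(np.abs(model.x))
        j = np.argmin(np.abs(model.y))
        assert model.density[i, j] == pytest.approx(1 / (2 * np.pi), rel=1e-3)
        # falls off as exp(-r^2/2)
        r_idx = np.argmin(np.abs(model.x - 1.0))
        assert model.density[r_idx, j] == pytest.approx(
            np.exp(-0.5) / (2 * np.pi), rel=1e-2
        )

    def test_repeated_point_equals_single(self):
        m1 = evaluate_kde(np.zeros((1, 2)), I2, grid_n=101)
        m5 = evaluate_kde(np.zeros((5, 2)), I2, grid_n=101)
        assert np.allclose(m1.density, m5.density)

    def test_mass_conservation(self, rng):
        pts = rng.multivariate_normal([0, 0], [[1.0, 0.4], [0.4, 0.7]], 500)
        model = evaluate_kde(pts)
        assert model.integral() == pytest.approx(1.0, abs=0.01)
        assert np.all(model.density >= 0)


class TestIseStatistic:
    def test_identical_samples_zero(self, rng):
        A = rng.normal(size=(20, 2))
        assert ise_statistic(A, A, I2, I2) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        # single points distance d apart, H = I each: the convolution
        # identity gives T = (2 - 2 exp(-d^2/4)) / (4 pi)
        for d in (0.3, 1.0, 2.5):
            T = ise_statistic([[0.0, 0.0]], [[d, 0.0]], I2, I2)
            assert T == pytest.approx((2 - 2 * np.exp(-d * d / 4)) / (4 * np.pi), rel=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        A = rng.normal(0, 1, (30, 2))
        B = rng.normal(0.4, 1.1, (25, 2))
        HA, HB = select_bandwidth(A), select_bandwidth(B)
        T = ise_statistic(A, B, HA, HB)
        g = np.linspace(-7, 7, 501)
        X, Y = np.meshgrid(g, g, indexing="ij")
        grid = np.column_stack([X.ravel(), Y.ravel()])

        def mixture(pts, H):
            Hi = np.linalg.inv(H.H)
            norm = 1 / (2 * np.pi * np.sqrt(np.linalg.det(H.H)))
            dens = np.zeros(len(grid))
            for p in pts:
                dd = grid - p
                q = Hi[0, 0] * dd[:, 0] ** 2 + 2 * Hi[0, 1] * dd[:, 0] * dd[:, 1] + Hi[1, 1] * dd[:, 1] ** 2
                dens += np.exp(-q / 2)
            return dens * norm / len(pts)

        quad = ((mixture(A, HA) - mixture(B, HB)) ** 2).sum() * (g[1] - g[0]) ** 2
        assert T == pytest.approx(quad, rel=1e-3)

    def test_rotation_invariance(self, rng):
        A = rng.normal(0, 1, (40, 2))
        B = rng.normal(0.5, 0.8, (35, 2))
        R = _rot(0.7)
        T0 = ise_statistic(A, B, select_bandwidth(A), select_bandwidth(B))
        T1 = ise_statistic(A @ R.T, B @ R.T, select_bandwidth(A @ R.T), select_bandwidth(B @ R.T))
        assert T1 == pytest.approx(T0, rel=1e-9)


class TestPermutationTest:
    def _clouds(self, rng, n_f=4, n_pts=25, shift=0.0):
        return [
            rng.normal([shift, 0.0], 0.3, (n_pts, 2)) for _ in range(n_f)
        ]

    def test_identical_populations_p_one(self, rng):
        A = self._clouds(rng)
        res = kde_two_sample_test(A, [c.copy() for c in A], n_perm=99, seed=0)
        assert res["T_obs"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_separated_populations_minimal_p(self, rng):
        # unequal female counts (the complement relabeling is then invalid)
        # and enough females that no permutation reproduces the observed
        # split, so the add-one p-value reaches its floor
        A = self._clouds(rng, n_f=10)
        B = self._clouds(rng, n_f=9, shift=50.0)
        res = kde_two_sample_test(A, B, n_perm=199, seed=0)
        assert res["p_value"] <= 1.0 / (199 + 1)

    def test_seed_reproducibility(self, rng):
        A, B = self._clouds(rng), self._clouds(rng, shift=0.3)
        r1 = kde_two_sample_test(A, B, n_perm=99, seed=5)
        r2 = kde_two_sample_test(A, B, n_perm=99, seed=5)
        assert r1 == r2

    def test_too_few_females_rejected(self, rng):
        with pytest.raises(ValueError):
            kde_two_sample_test(self._clouds(rng, n_f=1), self._clouds(rng), n_perm=99)

    def test_point_unit_allowed(self, rng):
        res = kde_two_sample_test(
            self._clouds(rng, n_f=2), self._clouds(rng, n_f=2), n_perm=99, seed=3, unit="point"
        )
        assert 0 < res["p_value"] <= 1


class TestFdrAdjust:
    def test_hand_applied_bh(self):
        # step-up: p_(i) * m / i, enforced monotone from the largest rank
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_inputs_unchanged(self):
        assert fdr_adjust([0.5, 0.5, 0.5, 0.5]) == pytest.approx([0.5] * 4)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone transform of the raw ordering
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestPairwiseComparison:
    def _study_clouds(self, rng, n_pops=4, n_f=6, outlier=None):
        clouds = {}
        for i in range(n_pops):
            shift = 1.2 if outlier == i else 0.0
            clouds[f"P{i}"] = [
                rng.normal([shift, 0.0], 0.25, (20, 2)) for _ in range(n_f)
            ]
        return clouds

    def test_pair_count(self, rng):
        table = pairwise_population_comparison(
            self._study_clouds(rng, n_pops=6), n_perm=99, seed=1
        )
        assert len(table.table) == 15  # C(6, 2)
        assert np.all(table.table["p_adj"] >= table.table["p_raw"] - 1e-12)
        m = table.matrix()
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)

    def test_planted_outlier_dominates_significance(self, rng):
        table = pairwise_population_comparison(
            self._study_clouds(rng, n_pops=4, outlier=0), n_perm=199, seed=2
        ).table
        sig = table[table["significant"]]
        assert len(sig) > 0
        assert all(("P0" == r.pop_a) or ("P0" == r.pop_b) for r in sig.itertuples())

    def test_exclusion_recomputes_fdr(self, rng):
        clouds = self._study_clouds(rng, n_pops=4, outlier=0)
        full = pairwise_population_comparison(clouds, n_perm=99, seed=3)
        reduced = pairwise_population_comparison(clouds, n_perm=99, seed=3, exclude=("P0",))
        assert len(reduced.table) == 3  # C(3, 2)
        assert "P0" not in set(reduced.table.pop_a) | set(reduced.table.pop_b)

    def test_min_n_eligibility(self, rng):
        clouds = self._study_clouds(rng, n_pops=3)
        clouds["tiny"] = [rng.normal(0, 0.3, (20, 2))]
        table = pairwise_population_comparison(clouds, min_n=4, n_perm=99, seed=0)
        assert "tiny" not in table.n_females
        with pytest.raises(ValueError):
            pairwise_population_comparison({"a": clouds["P0"]}, n_perm=99)


class TestPercentileContours:
    def test_gaussian_contours_nest_and_hold_mass(self, rng):
        pts = rng.standard_normal((400, 2))
        model = evaluate_kde(pts)
        regions = percentile_contours(model, percentiles=[25, 50, 75])
        masks = {r["percentile"]: r["mask"] for r in regions}
        assert np.all(masks[75] <= masks[50])
        assert np.all(masks[50] <= masks[25])
        masses = {r["percentile"]: r["mass"] for r in regions}
        assert masses[75] == pytest.approx(0.25, abs=0.02)
        assert masses[50] == pytest.approx(0.50, abs=0.02)
        assert masses[25] == pytest.approx(0.75, abs=0.02)

    def test_percentile_zero_covers_support(self, rng):
        model = evaluate_kde(rng.standard_normal((100, 2)))
        region = percentile_contours(model, percentiles=[0])[0]
        assert region["mass"] == pytest.approx(model.integral(), rel=1e-6)
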