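"""Deconvolution pipeline: LOF, clustering, grouping and composition,
validated against independent brute-force oracles."""

import warnings

import numpy as np
import pytest

from baccam.deconvolve import (
    DeconvolutionConfig,
    Mode,
    calibrate_cutoff,
    cluster_1d,
    deconvolute,
    fit_gmm_1d,
    full_on_off_check,
    group_clusters,
    kmeans_1d,
    lof_detect,
    lof_scores,
    oracle_threshold,
    reassign_outliers,
)
from baccam.grid import BitGrid
from baccam.readout import RatioTable
from oracles import brute_force_kmeans_1d, brute_force_lof, brute_force_threshold


def _ratio_table(values, channel="blue"):
    values = np.asarray(values, dtype=float)
    coverage = np.where(np.isnan(values), 0, 100)
    return RatioTable(channel=channel, values=values, coverage=coverage)


class TestLOF:
    @pytest.mark.parametrize("n,k", [(8, 2), (12, 3), (20, 5), (20, 19)])
    def test_matches_brute_force_definition(self, rng, n, k):
        for _ in range(5):
            x = rng.random(n)
            mine = lof_scores(x, k)
            oracle = brute_force_lof(list(x), k)
            np.testing.assert_allclose(mine, oracle, rtol=1e-9, atol=1e-9)

    def test_matches_brute_force_with_duplicates(self, rng):
        x = np.array([0.0, 0.0, 0.0, 0.1, 0.1, 0.5, 0.9, 0.9, 0.9, 0.9])
        mine = lof_scores(x, 3)
        oracle = brute_force_lof(list(x), 3)
        for m, o in zip(mine, oracle):
            if np.isinf(o):
                assert np.isinf(m)
            else:
                assert m == pytest.approx(o, abs=1e-9)

    def test_matches_sklearn_on_distinct_values(self, rng):
        from sklearn.neighbors import LocalOutlierFactor

        x = np.sort(rng.random(40))
        k = 10
        mine = lof_scores(x, k)
        ref = LocalOutlierFactor(n_neighbors=k).fit(x.reshape(-1, 1))
        np.testing.assert_allclose(mine, -ref.negative_outlier_factor_, rtol=1e-6)

    def test_identical_values_all_inliers(self):
        res = lof_detect(np.full(96, 0.25), n_neighbors=20)
        assert (res.labels == 1).all()

    def test_unique_far_point_is_the_only_outlier(self, rng):
        x = np.concatenate([rng.uniform(0.0, 0.1, 95), [0.9]])
        res = lof_detect(x, n_neighbors=20)
        assert res.labels[-1] == -1
        assert res.n_outliers == 1

    def test_too_few_points_warns_all_inliers(self):
        with pytest.warns(UserWarning, match="inliers"):
            res = lof_detect(np.arange(5.0), n_neighbors=20)
        assert (res.labels == 1).all()


class TestReassignment:
    def test_no_outliers_is_identity(self, rng):
        x = rng.random(10)
        out = reassign_outliers(x, np.ones(10, dtype=int))
        np.testing.assert_array_equal(out, x)

    def test_nearest_inlier_and_low_tie_rule(self):
        x = np.array([0.1, 0.2, 0.9])
        labels = np.array([1, 1, -1])
        assert reassign_outliers(x, labels)[2] == 0.2
        # exact tie between 0.25 and 0.75 resolves to the lower value
        x2 = np.array([0.25, 0.75, 0.5])
        labels2 = np.array([1, 1, -1])
        assert reassign_outliers(x2, labels2)[2] == 0.25

    def test_idempotent(self, rng):
        x = rng.random(30)
        labels = np.where(x > 0.8, -1, 1)
        once = reassign_outliers(x, labels)
        twice = reassign_outliers(once, labels)
        np.testing.assert_array_equal(once, twice)

    def test_zero_inliers_warns_identity(self):
        x = np.array([0.1, 0.2])
        with pytest.warns(UserWarning, match="no inliers"):
            out = reassign_outliers(x, np.array([-1, -1]))
        np.testing.assert_array_equal(out, x)


class TestKMeans1D:
    def test_simple_partition(self):
        labels = kmeans_1d(np.array([0, 0, 0, 1, 1, 1.0]), 2)
        assert list(labels) == [0, 0, 0, 1, 1, 1]

    @pytest.mark.parametrize("n,k", [(6, 2), (9, 3), (12, 2), (12, 3), (12, 4)])
    def test_matches_exhaustive_contiguous_partition(self, rng, n, k):
        for _ in range(10):
            x = rng.random(n)
            labels = kmeans_1d(x, k)
            sse = sum(
                ((x[labels == c] - x[labels == c].mean()) ** 2).sum()
                for c in range(k)
            )
            best_sse, best_labels = brute_force_kmeans_1d(list(x), k)
            assert sse == pytest.approx(best_sse, abs=1e-9)
            assert list(labels) == best_labels

    def test_never_worse_than_sklearn(self, rng):
        from sklearn.cluster import KMeans

        x = rng.random(40)
        labels = kmeans_1d(x, 3)
        sse = sum(
            ((x[labels == c] - x[labels == c].mean()) ** 2).sum() for c in range(3)
        )
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(x.reshape(-1, 1))
        assert sse <= km.inertia_ + 1e-9

    def test_affine_equivariance(self, rng):
        x = rng.random(30)
        labels = kmeans_1d(x, 3)
        labels_affine = kmeans_1d(3.0 * x + 1.0, 3)
        assert list(labels) == list(labels_affine)


class TestGMM:
    def test_single_component_closed_form(self, rng):
        x = rng.random(50)
        m = fit_gmm_1d(x, 1)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-12)

    def test_two_tight_groups(self, rng):
        x = np.concatenate(
            [rng.normal(0.05, 0.005, 48), rng.normal(0.95, 0.005, 48)]
        )
        m = fit_gmm_1d(x, 2)
        assert abs(m.means[0] - 0.05) < 0.02 and abs(m.means[1] - 0.95) < 0.02
        assert m.weights.sum() == pytest.approx(1.0)
        assert (m.variances > 0).all()

    def test_log_likelihood_monotone(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.05, 40), rng.normal(0.7, 0.1, 56)])
        m = fit_gmm_1d(x, 3)
        hist = m.settings["ll_history"]
        assert len(hist) >= 2
        assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_three_component_recovery(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            x = np.concatenate([r.normal(mu, 0.03, 32) for mu in (0.1, 0.5, 0.9)])
            m = fit_gmm_1d(x, 3)
            se = 0.03 / np.sqrt(32)
            if all(
                abs(m.means[i] - mu) < 3 * se
                for i, mu in enumerate((0.1, 0.5, 0.9))
            ):
                hits += 1
        assert hits >= 19

    def test_matches_sklearn_on_separated_data(self, rng):
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(0.1, 0.02, 50), rng.normal(0.8, 0.03, 46)])
        mine = fit_gmm_1d(x, 2)
        ref = GaussianMixture(2, random_state=0, n_init=3).fit(x.reshape(-1, 1))
        np.testing.assert_allclose(
            mine.means, np.sort(ref.means_.ravel()), atol=1e-3
        )

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_gmm_1d(np.array([0.0, 0.0, 1.0, 1.0]), 3)


class TestDensityMethods:
    def test_dbscan_two_groups(self, rng):
        x = np.concatenate([rng.normal(0.1, 0.01, 20), rng.normal(0.6, 0.01, 20)])
        m = cluster_1d(x, method="dbscan", eps=0.2, min_samples=5)
        assert m.k == 2
        assert m.means[1] - m.means[0] == pytest.approx(0.5, abs=0.05)

    def test_noise_absorbed_to_nearest_cluster(self, rng):
        x = np.concatenate(
            [rng.normal(0.1, 0.005, 20), rng.normal(0.9, 0.005, 20), [0.8]]
        )
        m = cluster_1d(x, method="dbscan", eps=0.05, min_samples=5)
        assert m.k == 2
        assert m.labels[-1] == 1  # the 0.8 straggler joins the high cluster

    def test_all_noise_falls_back_to_single_cluster(self):
        x = np.linspace(0, 1, 8)
        with pytest.warns(UserWarning, match="single cluster"):
            m = cluster_1d(x, method="dbscan", eps=0.01, min_samples=5)
        assert m.k == 1

    def test_optics_on_separated_groups(self, rng):
        # the xi extraction may split a group into sub-clusters, but no
        # cluster may straddle the wide gap between the two groups
        x = np.concatenate([rng.normal(0.1, 0.01, 30), rng.normal(0.8, 0.01, 30)])
        m = cluster_1d(x, method="optics")
        assert m.k >= 2
        assert m.means.min() < 0.2 and m.means.max() > 0.7
        assert not ((m.means > 0.2) & (m.means < 0.7)).any()


class TestModeAndGrouping:
    @pytest.mark.parametrize(
        "means,mode",
        [
            ([0.8, 0.9], Mode.ALL_ON),
            ([0.02, 0.05], Mode.ALL_OFF),
            ([0.1, 0.9], Mode.MIXED),
        ],
    )
    def test_full_on_off_rules(self, means, mode):
        from baccam.deconvolve import ClusterModel

        model = ClusterModel(
            method="kmeans", k=len(means), means=np.array(means),
            labels=np.arange(len(means)),
        )
        assert full_on_off_check(model, cutoff=0.5) is mode

    def test_blue_groups_lowest_cluster_off(self):
        from baccam.deconvolve import ClusterModel

        labels = np.array([0, 1, 2, 0, 1, 2])
        model = ClusterModel(
            method="gmm", k=3, means=np.array([0.05, 0.5, 0.9]), labels=labels
        )
        np.testing.assert_array_equal(
            group_clusters(model, "blue"), [0, 1, 1, 0, 1, 1]
        )
        np.testing.assert_array_equal(
            group_clusters(model, "red"), [0, 0, 1, 0, 0, 1]
        )

    def test_red_with_two_clusters_splits_lowest(self):
        from baccam.deconvolve import ClusterModel

        model = ClusterModel(
            method="gmm", k=2, means=np.array([0.1, 0.9]),
            labels=np.array([0, 1, 0]),
        )
        np.testing.assert_array_equal(group_clusters(model, "red"), [0, 1, 0])

    def test_single_cluster_mixed_is_error(self):
        from baccam.deconvolve import ClusterModel

        model = ClusterModel(
            method="kmeans", k=1, means=np.array([0.5]), labels=np.zeros(4, int)
        )
        with pytest.raises(ValueError):
            group_clusters(model, "blue")

    def test_calibrate_cutoff_midpoint(self):
        from baccam.deconvolve import ClusterModel

        models = [
            ClusterModel("gmm", 2, np.array([0.1, 0.9]), np.arange(2)),
            ClusterModel("gmm", 2, np.array([0.2, 0.8]), np.arange(2)),
        ]
        assert calibrate_cutoff(models) == pytest.approx(0.5)


class TestDeconvolute:
    def test_separable_values_decode_exactly(self, rng):
        truth = BitGrid.random(rng)
        values = np.where(truth.flat() == 1, 0.92, 0.06) + rng.normal(0, 0.01, 96)
        res = deconvolute(_ratio_table(values), truth=truth)
        assert res.mode is Mode.MIXED
        assert res.accuracy == 1.0

    def test_permutation_equivariance(self, rng):
        truth = BitGrid.random(rng)
        values = np.where(truth.flat() == 1, 0.9, 0.1) + rng.normal(0, 0.02, 96)
        base = deconvolute(_ratio_table(values), truth=truth)
        perm = rng.permutation(96)
        shuffled = deconvolute(
            _ratio_table(values[perm]),
            truth=BitGrid.from_flat(truth.flat()[perm]),
        )
        unshuffled = np.empty(96, dtype=int)
        unshuffled[perm] = shuffled.grid.flat()
        np.testing.assert_array_equal(unshuffled, base.grid.flat())

    def test_missing_wells_become_zero_with_warning(self, rng):
        truth = BitGrid.random(rng)
        values = np.where(truth.flat() == 1, 0.9, 0.1).astype(float)
        values[[3, 40]] = np.nan
        with pytest.warns(UserWarning, match="MISSING"):
            res = deconvolute(_ratio_table(values), truth=truth)
        assert res.grid.flat()[3] == 0 and res.grid.flat()[40] == 0

    def test_all_missing_is_all_off(self):
        with pytest.warns(UserWarning, match="every well"):
            res = deconvolute(_ratio_table(np.full(96, np.nan)))
        assert res.mode is Mode.ALL_OFF
        assert res.grid == BitGrid.zeros()

    def test_report_is_json_serializable(self, rng):
        import json

        truth = BitGrid.random(rng)
        values = np.where(truth.flat() == 1, 0.9, 0.1) + rng.normal(0, 0.02, 96)
        res = deconvolute(_ratio_table(values), truth=truth)
        rep = res.report()
        json.dumps(rep)
        assert rep["mode"] == "mixed" and len(rep["wells"]) == 96


class TestOracleThreshold:
    def test_separable(self, rng):
        truth = BitGrid.random(rng)
        values = np.where(truth.flat() == 1, 0.9, 0.1)
        thr, acc = oracle_threshold(_ratio_table(values), truth)
        assert acc == 1.0 and 0.1 < thr < 0.9

    def test_constant_truth_gives_prevalence(self, rng):
        values = rng.random(96)
        thr, acc = oracle_threshold(_ratio_table(values), BitGrid.zeros())
        assert acc == 1.0  # threshold above max achieves all-zero calls

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            values = rng.random(96)
            truth = BitGrid.random(rng)
            thr, acc = oracle_threshold(_ratio_table(values), truth)
            bt, bacc = brute_force_threshold(list(values), list(truth.flat()))
            assert acc == pytest.approx(bacc)
            assert thr == pytest.approx(bt)
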