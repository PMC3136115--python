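"""Partition validity: standardization, distances, k-means/PAM, silhouettes."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

import ermimap as em
from ermimap.errors import ConfigError, InputError, InsufficientDataError
from ermimap.validity import (
    kmeans,
    kmedoids,
    pairwise_distances,
    partition,
    silhouette,
    validity_scan,
)
from ermimap.validity import _pam_build


def brute_force_silhouette(labels, D):
    """Textbook double loop, no vectorization."""
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            widths[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        widths[i] = (b - a) / max(a, b)
    return widths, widths.mean()


class TestStandardize:
    def test_two_point_population_sd(self):
        out = em.standardize(pd.DataFrame({"x": [1.0, 3.0], "y": [0.0, 2.0]}))
        np.testing.assert_allclose(out["x"], [-1.0, 1.0])

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            out = em.standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0],
                                               "c": [5.0, 5.0, 5.0]}))
        assert (out["c"] == 0).all()

    def test_columns_centered_and_scaled(self, rng):
        z = em.standardize(pd.DataFrame(rng.normal(3, 2, (100, 36))))
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0, ddof=0) - 1).max() < 1e-9

    def test_single_home_rejected(self):
        with pytest.raises(InsufficientDataError):
            em.standardize(pd.DataFrame({"x": [1.0]}))


class TestDistances:
    def test_known_values(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert pairwise_distances(pts, "euclidean")[0, 1] == pytest.approx(5.0)
        assert pairwise_distances(pts, "manhattan")[0, 1] == pytest.approx(7.0)
        corr = pairwise_distances(np.array([[1.0, 2, 3], [2.0, 4, 6]]),
                                  "correlation")
        assert corr[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_properties(self, rng):
        D = pairwise_distances(rng.standard_normal((20, 5)), "manhattan")
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all()

    def test_unknown_metric(self):
        with pytest.raises(ConfigError):
            pairwise_distances(np.eye(3), "minkowski-7")


class TestKmeans:
    def test_separable_blobs(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (25, 3))])
        labels = kmeans(x, 2, seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic_and_nonempty(self, rng):
        x = rng.standard_normal((40, 4))
        a = kmeans(x, 5, seed=3)
        b = kmeans(x, 5, seed=3)
        assert np.array_equal(a, b)
        assert len(np.unique(a)) == 5

    def test_sklearn_cross_check(self, rng):
        """On well-separated blobs our Lloyd agrees with scikit-learn."""
        skl = pytest.importorskip("sklearn.cluster")
        x = np.vstack([rng.normal(c, 0.2, (15, 4)) for c in (0, 4, 8)])
        ours = kmeans(x, 3, seed=0)
        ref = skl.KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(x)
        # same partition up to label permutation
        assert len({(o, r) for o, r in zip(ours, ref)}) == 3

    def test_k_bounds(self, rng):
        with pytest.raises(ConfigError):
            kmeans(rng.standard_normal((5, 2)), 7)


class TestKmedoids:
    def test_exhaustive_two_medoid_oracle(self, rng):
        """PAM cost on n=5 equals the optimum over all medoid pairs."""
        for _ in range(10):
            D = pairwise_distances(rng.standard_normal((5, 3)), "euclidean")
            labels, medoids = kmedoids(D, 2, return_medoids=True)
            cost = D[np.arange(5), np.array(medoids)[labels]].sum()
            best = min(
                np.minimum(D[:, m1], D[:, m2]).sum()
                for m1, m2 in combinations(range(5), 2)
            )
            assert cost == pytest.approx(best, abs=1e-12)

    def test_swap_never_worse_than_build(self, rng):
        x = rng.standard_normal((60, 6))
        D = pairwise_distances(x, "euclidean")
        build = _pam_build(D, 4)
        build_cost = D[:, build].min(axis=1).sum()
        labels, medoids = kmedoids(D, 4, return_medoids=True)
        final_cost = D[:, medoids].min(axis=1).sum()
        assert final_cost <= build_cost + 1e-9

    def test_deterministic(self, rng):
        D = pairwise_distances(rng.standard_normal((30, 4)), "manhattan")
        assert np.array_equal(kmedoids(D, 3, seed=1), kmedoids(D, 3, seed=1))

    def test_unknown_algorithm(self, rng):
        with pytest.raises(ConfigError):
            partition(rng.standard_normal((10, 2)), 2, algorithm="dbscan")


class TestSilhouette:
    def test_far_separated_blobs(self, rng):
        x = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(50, 0.05, (10, 2))])
        D = pairwise_distances(x, "euclidean")
        _, avg = silhouette([0] * 10 + [1] * 10, D)
        assert avg > 0.9

    def test_four_point_hand_calculation(self):
        # points on a line: 0, 1, 10, 12; partitions {0,1} and {10,12}
        pts = np.array([[0.0], [1.0], [10.0], [12.0]])
        D = pairwise_distances(pts, "euclidean")
        widths, avg = silhouette([0, 0, 1, 1], D)
        # home 0: a=1, b=(10+12)/2=11 -> 10/11, etc.
        expected = [(11 - 1) / 11, (10 - 1) / 10, (9.5 - 2) / 9.5,
                    (11.5 - 2) / 11.5]
        np.testing.assert_allclose(widths, expected, atol=1e-12)
        assert avg == pytest.approx(np.mean(expected), abs=1e-12)

    def test_matches_brute_force_battery(self, rng):
        """Exhaustive comparison on every instance with n <= 12."""
        for n in range(4, 13):
            for trial in range(4):
                D = pairwise_distances(rng.standard_normal((n, 3)), "euclidean")
                k = int(rng.integers(2, min(n, 5)))
                labels = rng.integers(0, k, n)
                labels[:k] = np.arange(k)  # all partitions non-empty
                got_w, got_avg = silhouette(labels, D)
                want_w, want_avg = brute_force_silhouette(labels, D)
                np.testing.assert_allclose(got_w, want_w, atol=1e-12)
                assert got_avg == pytest.approx(want_avg, abs=1e-12)

    def test_sklearn_cross_check(self, rng):
        skm = pytest.importorskip("sklearn.metrics")
        x = rng.standard_normal((40, 5))
        D = pairwise_distances(x, "euclidean")
        labels = np.array([i % 3 for i in range(40)])
        _, avg = silhouette(labels, D)
        assert avg == pytest.approx(
            skm.silhouette_score(D, labels, metric="precomputed"), abs=1e-10
        )

    def test_invariances(self, rng):
        D = pairwise_distances(rng.standard_normal((25, 4)), "euclidean")
        labels = np.array([i % 4 for i in range(25)])
        _, avg = silhouette(labels, D)
        _, relabeled = silhouette((labels + 2) % 4, D)
        assert relabeled == pytest.approx(avg, abs=1e-12)
        _, scaled = silhouette(labels, 7.3 * D)
        assert scaled == pytest.approx(avg, abs=1e-12)

    def test_singleton_and_errors(self):
        D = pairwise_distances(np.arange(8.0).reshape(-1, 1), "euclidean")
        widths, _ = silhouette([0] + [1] * 7, D)
        assert widths[0] == 0.0
        with pytest.raises(InputError):
            silhouette([0] * 8, D)


class TestValidityScan:
    def test_planted_communities_flagged(self, rng):
        """Three well-separated home communities produce a strong k=3 signal."""
        x = np.vstack([rng.normal(c, 0.3, (30, 36)) for c in (0, 4, 8)])
        z = em.standardize(pd.DataFrame(x))
        res = validity_scan(z, ks=range(2, 6), metrics=["euclidean"],
                            algorithms=["kmeans", "kmedoids"], seed=0)
        flagged = res[res["flagged"]]
        assert not flagged.empty
        best = res.loc[res["avg_silhouette"].idxmax()]
        assert best["k"] == 3

    def test_unstructured_not_flagged(self):
        hm = em.spatially_unstructured(
            em.SynthConfig(n_homes=150, n_locales=10, seed=2)
        )
        z = em.standardize(em.log_transform(hm.conc))
        res = validity_scan(z, ks=range(2, 5), seed=0)
        assert not res["flagged"].any()

    def test_empty_grid_rejected(self, rng):
        z = em.standardize(pd.DataFrame(rng.standard_normal((20, 4))))
        with pytest.raises(ConfigError):
            validity_scan(z, ks=[])
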