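"""Weighted k-means, elbow selection, KDE and representative selection."""

import numpy as np
import pytest

import porescan as ps
from porescan.cluster import WeightedKDE, WeightedKMeans, elbow, find_representative, kde_fit
from porescan.errors import DegenerateKDEError, InvalidArgumentError

from oracles import brute_kmeans_inertia


def blobs(rng, centers, n_per=30, spread=0.05):
    pts = np.concatenate(
        [c + spread * rng.normal(size=(n_per, len(c))) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


class TestWeightedKMeans:
    def test_k1_closed_form(self, rng):
        x = rng.normal(size=(40, 3))
        w = rng.integers(1, 5, 40).astype(float)
        km = WeightedKMeans(1, random_state=0).fit(x, sample_weight=w)
        mean = np.average(x, axis=0, weights=w)
        np.testing.assert_allclose(km.cluster_centers_[0], mean, atol=1e-9)
        expected = float(np.sum(w * np.sum((x - mean) ** 2, axis=1)))
        assert km.inertia_ == pytest.approx(expected, rel=1e-9)

    def test_two_separated_blobs_exact(self, rng):
        x, truth = blobs(rng, [np.zeros(3), 10 * np.ones(3)])
        km = WeightedKMeans(2, random_state=0).fit(x)
        # same partition up to label swap
        assert len(set(zip(truth.tolist(), km.labels_.tolist()))) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_inertia_matches_partition_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=(8, 2))
        w = rng.integers(1, 4, 8).astype(float)
        km = WeightedKMeans(2, n_init=50, random_state=seed).fit(x, sample_weight=w)
        assert km.inertia_ == pytest.approx(brute_kmeans_inertia(x, w, 2), rel=1e-9)

    def test_weight_equals_replication(self, rng):
        x = rng.normal(size=(12, 3))
        w = rng.integers(1, 5, 12)
        replicated = np.repeat(x, w, axis=0)
        km_w = WeightedKMeans(3, n_init=20, random_state=1).fit(
            x, sample_weight=w.astype(float)
        )
        km_r = WeightedKMeans(3, n_init=20, random_state=1).fit(replicated)
        assert km_w.inertia_ == pytest.approx(km_r.inertia_, rel=1e-8)
        np.testing.assert_allclose(
            np.sort(km_w.cluster_centers_, axis=0),
            np.sort(km_r.cluster_centers_, axis=0),
            atol=1e-8,
        )

    def test_populations_sum_to_total_weight(self, rng):
        x = rng.normal(size=(50, 3))
        w = rng.integers(1, 9, 50).astype(float)
        km = WeightedKMeans(4, random_state=0).fit(x, sample_weight=w)
        assert km.populations_.sum() == pytest.approx(w.sum())
        assert (np.diff(km.populations_) <= 1e-12).all()  # descending order

    def test_assignments_are_nearest_centroid(self, rng):
        x = rng.normal(size=(60, 3))
        km = WeightedKMeans(3, random_state=0).fit(x)
        np.testing.assert_array_equal(km.labels_, km.predict(x))

    def test_k_exceeding_distinct_points_rejected(self):
        x = np.tile([[0.0, 0.0]], (5, 1))
        with pytest.raises(InvalidArgumentError):
            WeightedKMeans(2).fit(x)

    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.normal(size=(100, 3))
        a = WeightedKMeans(4, random_state=7).fit(x)
        b = WeightedKMeans(4, random_state=7).fit(x)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        assert a.inertia_ == b.inertia_

    def test_sklearn_compat_get_params(self):
        km = WeightedKMeans(5, random_state=3)
        assert km.get_params()["n_clusters"] == 5
        km.set_params(n_clusters=2)
        assert km.n_clusters == 2


class TestElbow:
    def test_three_separated_blobs(self, rng):
        x, _ = blobs(rng, [np.zeros(3), [5, 0, 0], [0, 5, 0]], n_per=50)
        res = elbow(x, random_state=0)
        assert res.k_opt == 3
        assert not res.low_confidence

    def test_three_collinear_blobs(self, rng):
        """Centroid arrangement must not fool the knee detection."""
        x, _ = blobs(rng, [np.zeros(3), [4, 0, 0], [8, 0, 0]], n_per=50)
        res = elbow(x, random_state=0)
        assert res.k_opt == 3

    def test_single_blob_low_confidence(self, rng):
        x = rng.normal(size=(200, 3))
        res = elbow(x, random_state=0)
        assert res.low_confidence

    def test_inertia_non_increasing(self, rng):
        x, _ = blobs(rng, [np.zeros(3), [3, 0, 0]], n_per=40)
        res = elbow(x, random_state=0)
        assert (np.diff(res.inertias) <= 1e-8).all()


class TestKDE:
    def test_mode_near_sample_mean(self):
        """KDE mode of a Gaussian sample sits at the center (20 seeds)."""
        modes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.0, 1.0, (300, 3))
            kde = kde_fit(x)
            grid = rng.normal(0.0, 0.5, (500, 3))
            modes.append(grid[np.argmax(kde.log_density(grid))])
        modes = np.asarray(modes)
        se = modes.std(axis=0, ddof=1) / np.sqrt(len(modes))
        assert np.all(np.abs(modes.mean(axis=0)) < 3 * se + 0.1)

    def test_1d_density_integrates_to_one(self, rng):
        x = rng.normal(size=(400, 1))
        w = rng.integers(1, 5, 400).astype(float)
        kde = kde_fit(x, sample_weight=w)
        grid = np.linspace(-8, 8, 4001)[:, None]
        integral = np.trapezoid(kde.density(grid).ravel(), grid.ravel())
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_weight_scaling_invariance(self, rng):
        x = rng.normal(size=(100, 3))
        w = rng.integers(1, 6, 100).astype(float)
        a = kde_fit(x, sample_weight=w)
        b = kde_fit(x, sample_weight=3.0 * w)
        pts = rng.normal(size=(20, 3))
        np.testing.assert_allclose(a.density(pts), b.density(pts), rtol=1e-10)

    def test_singleton_cluster_degenerate(self):
        with pytest.raises(DegenerateKDEError):
            kde_fit(np.array([[1.0, 2.0, 3.0]]))

    def test_fixed_bandwidth(self, rng):
        x = rng.normal(size=(50, 2))
        kde = WeightedKDE(bandwidth=0.25).fit(x)
        assert kde.bandwidth_ == 0.25


class TestRepresentative:
    def test_two_point_cluster_picks_heavier(self):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        kde = kde_fit(pts, sample_weight=np.array([1.0, 5.0]))
        rep = find_representative(pts, kde, weights=np.array([1.0, 5.0]))
        np.testing.assert_array_equal(rep.point, pts[1])

    def test_member_at_maximum_returned_exactly(self, rng):
        x = np.concatenate([np.zeros((1, 3)), rng.normal(0, 1.0, (400, 3))])
        kde = kde_fit(x)
        rep = find_representative(x, kde)
        # the located max is near 0; the planted member at the origin should win
        assert np.linalg.norm(rep.point) < np.linalg.norm(x[1:], axis=1).min() + 1.0

    def test_blob_center_recovered(self):
        """Representative lies near the blob center over 20 seeds."""
        reps = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(2.0, 0.5, (250, 3))
            kde = kde_fit(x)
            reps.append(find_representative(x, kde).point)
        reps = np.asarray(reps)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(reps.mean(axis=0) - 2.0) < 3 * se + 0.05)

    def test_map_to_frames_round_trip(self, tiny_campaign_config, tmp_path):
        """The representative's frames reproduce its tuple exactly."""
        trajs, _ = ps.simulate_campaign(tiny_campaign_config)
        frames = [ps.prepare_replica_frames(t, 1.0) for t in trajs[:6]]
        ts = ps.merge_weights(ps.build_tuples(frames, "all_cross"), 6)
        space = ps.scale(ts, 1.0)
        km = WeightedKMeans(2, random_state=0).fit(space.scaled, sample_weight=space.weights)
        reps = ps.representatives_for(space, km)
        lookup = {t.replica_id: t for t in trajs}

        def loader(rid, fi):
            return lookup[rid].frame(fi)

        for rep in reps:
            x, y = ps.map_to_frames(rep, loader, tmp_path)
            raw = space.tuples.values[rep.tuple_index]
            assert ps.rmsd(x, y) == pytest.approx(raw[0], abs=1e-6)

    def test_map_to_frames_missing_file(self, tiny_campaign_config):
        def loader(rid, fi):
            raise IOError(f"trajectory file not found: {rid}.pdb")

        rep = ps.Representative(0, 0, 0, np.zeros(3), 1.0, 0.1, np.zeros(3),
                                (("r000", 1), ("r001", 2)))
        with pytest.raises(IOError, match="r000"):
            ps.map_to_frames(rep, loader)
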