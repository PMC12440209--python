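"""SOM training, k selection, centroid store and cluster assignment."""

import numpy as np
import pytest

from glycloop.errors import ProfilingError
from glycloop.planted import make_planted_dataset, recovery_rate
from glycloop.profiling import (
    CentroidStore, EVENT_CLASSES, SYSTEMS, assign_clusters,
    best_matching_unit, build_profile_index, choose_k, som_update_step,
    train_som,
)


class TestSom:
    def test_identical_inputs_collapse_weights(self):
        v = np.array([2.0, -1.0, 0.5])
        som = train_som(np.tile(v, (60, 1)), epochs=300, seed=0)
        assert np.max(np.abs(som.weights - v)) < 1e-6

    def test_update_step_moves_bmu_toward_input(self):
        rng = np.random.default_rng(1)
        som = train_som(rng.normal(size=(150, 4)), epochs=5, seed=1)
        x = rng.normal(size=4)
        bmu = best_matching_unit(som, x)
        j = bmu[0] * som.cols + bmu[1]
        before = np.linalg.norm(som.weights[j] - x)
        som_update_step(som, x, lr=0.3, radius=1.0)
        after = np.linalg.norm(som.weights[j] - x)
        assert after < before

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 5))
        w1 = train_som(X, epochs=20, seed=42).weights
        w2 = train_som(X, epochs=20, seed=42).weights
        np.testing.assert_array_equal(w1, w2)

    def test_empty_input_rejected(self):
        with pytest.raises(ProfilingError):
            train_som(np.empty((0, 3)))


class TestBmu:
    @pytest.fixture
    def som(self):
        rng = np.random.default_rng(3)
        return train_som(rng.normal(size=(150, 3)), epochs=10, seed=3)

    def test_exact_weight_match(self, som):
        r, c = 3, 4
        v = som.weights[r * som.cols + c]
        assert best_matching_unit(som, v) == (r, c)

    def test_tie_breaks_lexicographic(self, som):
        # make neurons (1,9) and (2,0) both exact matches of a far probe
        probe = np.array([100.0, 100.0, 100.0])
        a, b = 1 * som.cols + 9, 2 * som.cols + 0
        som.weights[a] = probe
        som.weights[b] = probe
        assert best_matching_unit(som, probe) == (1, 9)

    def test_is_argmin(self, som):
        rng = np.random.default_rng(4)
        v = rng.normal(size=3)
        r, c = best_matching_unit(som, v)
        d_best = np.linalg.norm(som.weights[r * som.cols + c] - v)
        d_all = np.linalg.norm(som.weights - v, axis=1)
        assert d_best <= d_all.min() + 1e-12

    def test_dimension_mismatch(self, som):
        with pytest.raises(ProfilingError):
            best_matching_unit(som, np.zeros(7))


class TestChooseK:
    @pytest.mark.parametrize("n_blobs", [2, 3])
    def test_recovers_blob_count(self, n_blobs):
        rng = np.random.default_rng(5)
        centers = [np.full(4, 8.0 * i) for i in range(n_blobs)]
        X = np.vstack([rng.normal(c, 0.4, size=(60, 4)) for c in centers])
        som = train_som(X, epochs=60, seed=5)
        k, diag = choose_k(som.weights, seed=5)
        assert k == n_blobs
        assert set(diag["sse"]) == set(range(2, 9))

    def test_degenerate_prototypes_fall_back_to_3(self):
        k, _ = choose_k(np.ones((50, 4)), seed=0)
        assert k == 3


class TestProfileIndex:
    def test_exactly_twelve_centroids(self, planted_dataset):
        store = build_profile_index(planted_dataset, seed=1, som_epochs=60)
        assert len(store.centroids) == 12
        for system in SYSTEMS:
            for ec in EVENT_CLASSES:
                assert sum(1 for (s, e, _) in store.centroids if s == system
                           and e == ec) == 3

    def test_deterministic_under_seed(self, planted_dataset):
        s1 = build_profile_index(planted_dataset, seed=4, som_epochs=60)
        s2 = build_profile_index(planted_dataset, seed=4, som_epochs=60)
        for key in s1.centroids:
            np.testing.assert_array_equal(s1.centroids[key], s2.centroids[key])

    def test_planted_subgroups_recovered(self, planted_dataset):
        build_profile_index(planted_dataset, seed=2, som_epochs=200)
        assert recovery_rate(planted_dataset, "S1") >= 0.9
        assert recovery_rate(planted_dataset, "S2") >= 0.9

    def test_empty_subset_raises_naming_it(self):
        ds = make_planted_dataset(n_per_subgroup=10, seed=0)
        for inst in ds:
            inst.label_hypo = 0  # no hypoglycemia events at all
        with pytest.raises(ProfilingError, match="S1/event"):
            build_profile_index(ds, seed=0, som_epochs=10)

    def test_round_trip_serialization(self, planted_dataset):
        store = build_profile_index(planted_dataset, seed=3, som_epochs=60)
        again = CentroidStore.from_dict(store.to_dict())
        for key in store.centroids:
            np.testing.assert_array_equal(store.centroids[key],
                                          again.centroids[key])
        np.testing.assert_array_equal(store.norm_mean, again.norm_mean)


@pytest.fixture(scope="module")
def store(planted_dataset):
    return build_profile_index(planted_dataset, seed=6, som_epochs=60)


class TestAssignment:

    def test_stored_centroid_maps_to_itself(self, store):
        key = ("S1", "event", 1)
        centroid = store.centroids[key]
        # invert the normalization to get a raw vector on the centroid
        raw = np.zeros(13)
        raw[store.feature_idx] = centroid * store.norm_sd + store.norm_mean
        ranked = assign_clusters(store, raw, "S1")
        assert ranked[0][0] == key
        assert ranked[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_ranking_is_complete_permutation(self, store, planted_dataset):
        v = planted_dataset[0].features.to_array()
        ranked = assign_clusters(store, v, "S2")
        assert sorted(k for k, _ in ranked) == sorted(store.system_keys("S2"))

    def test_distances_non_decreasing(self, store, planted_dataset):
        v = planted_dataset[1].features.to_array()
        d = [dist for _, dist in assign_clusters(store, v, "S1")]
        assert all(a <= b + 1e-12 for a, b in zip(d, d[1:]))

    def test_normalized_vector_rejected(self, store):
        with pytest.raises(ProfilingError, match="13-feature"):
            assign_clusters(store, np.zeros(12), "S1")

    def test_assignment_scale_invariant(self, planted_dataset):
        """Rescaling raw features leaves the ranking unchanged (z-scoring)."""
        store = build_profile_index(planted_dataset, seed=8, som_epochs=60)
        v = planted_dataset[2].features.to_array()
        r1 = [k for k, _ in assign_clusters(store, v, "S1")]

        import copy
        scaled = copy.deepcopy(planted_dataset)
        for inst in scaled:
            fv = inst.features
            fv.cgm_at_meal *= 10
            fv.hourly_means = tuple(h * 10 for h in fv.hourly_means)
        store2 = build_profile_index(scaled, seed=8, som_epochs=60)
        v2 = v.copy()
        v2[0] *= 10
        v2[1:7] *= 10
        r2 = [k for k, _ in assign_clusters(store2, v2, "S1")]
        assert r1 == r2
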