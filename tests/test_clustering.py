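"""Cosine k-means partition, silhouette evaluation and centroid assignment."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from plstates import (LeadingEigSeries, assign_to_centroids, fit_kmeans,
                      silhouette_score, sweep_k)


def unit(x):
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def jittered_cloud(rng, generators, reps, sigma=0.01):
    """Points scattered tightly around each generator direction."""
    obs, labels = [], []
    for i, g in enumerate(generators):
        pts = g[None, :] + rng.normal(0, sigma, size=(reps, g.size))
        obs.append(unit(pts))
        labels.append(np.full(reps, i))
    return np.vstack(obs), np.concatenate(labels)


class TestFitKmeans:
    def test_recovers_orthogonal_generators(self, rng):
        gens = np.eye(4)
        x, _ = jittered_cloud(rng, gens, reps=100)
        cset, seqs = fit_kmeans(x, 4, n_replicates=20, seed=0)
        sims = np.abs(cset.centroids @ gens.T)
        assert np.all(sims.max(axis=1) > 0.99)  # cosine distance < 0.01
        assert cset.fit_inertia < 4 * 100 * 1e-3

    def test_zero_noise_synthetic_agreement_is_perfect(self, noiseless_spec):
        """Scans that each hold one planted state produce eigenvectors
        exactly on the pattern directions; recovered labels agree with
        truth up to permutation (adjusted Rand index 1)."""
        from plstates import eigenvector_series, simulate_bold

        k = noiseless_spec.n_states
        eigs, truth_labels = [], []
        for state in range(1, k + 1):
            seq = np.full(noiseless_spec.n_samples, state)
            ts, _ = simulate_bold(noiseless_spec.replace(seed=state), seq)
            eigs.append(eigenvector_series(ts))
            truth_labels.append(np.full(noiseless_spec.n_samples - 2, state))
        cset, seqs = fit_kmeans(eigs, k, n_replicates=10, seed=3)
        ari = adjusted_rand_score(np.concatenate(truth_labels),
                                  np.concatenate([s.labels for s in seqs]))
        assert ari == 1.0

    def test_bitwise_deterministic_given_seed(self, rng):
        x, _ = jittered_cloud(rng, unit(rng.normal(size=(3, 8))), reps=40)
        c1, _ = fit_kmeans(x, 3, n_replicates=5, seed=9)
        c2, _ = fit_kmeans(x, 3, n_replicates=5, seed=9)
        assert np.array_equal(c1.centroids, c2.centroids)

    def test_states_ordered_by_descending_occupancy(self, rng):
        gens = unit(rng.normal(size=(3, 10)))
        obs, _ = jittered_cloud(rng, gens, reps=50)
        x = np.vstack([obs, unit(gens[2] + rng.normal(0, 0.01, (90, 10)))])
        _, seqs = fit_kmeans(x, 3, n_replicates=10, seed=1)
        occ = np.bincount(seqs[0].labels - 1, minlength=3)
        assert np.all(np.diff(occ) <= 0)

    def test_centroid_rows_unit_norm_and_sign_convention(self, noisy_scan):
        from plstates import eigenvector_series

        _, ts, _ = noisy_scan
        cset, _ = fit_kmeans(eigenvector_series(ts), 4,
                             n_replicates=10, seed=0)
        assert np.allclose(np.linalg.norm(cset.centroids, axis=1), 1.0,
                           atol=1e-9)
        assert np.all(cset.centroids.sum(axis=1) <= 1e-9)

    def test_k_exceeding_observations_rejected(self, rng):
        x = unit(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="k="):
            fit_kmeans(x, 10, n_replicates=2, seed=0)

    def test_label_permutation_invariance(self, rng):
        """Relabeling (reordering) the generators leaves the recovered
        centroid set unchanged as a set."""
        gens = unit(rng.normal(size=(3, 12)))
        x, _ = jittered_cloud(rng, gens, reps=60)
        perm = [2, 0, 1]
        x_perm, _ = jittered_cloud(np.random.default_rng(12345),
                                   gens[perm], reps=60)
        c1, _ = fit_kmeans(x, 3, n_replicates=10, seed=4)
        c2, _ = fit_kmeans(x_perm, 3, n_replicates=10, seed=4)
        sims = np.abs(c1.centroids @ c2.centroids.T)
        assert np.all(sims.max(axis=1) > 0.999)


class TestSweepK:
    def test_k_2_to_20_yields_19_partitions(self, rng):
        gens = unit(rng.normal(size=(6, 25)))
        x, _ = jittered_cloud(rng, gens, reps=10, sigma=0.05)
        sweep = sweep_k(x, 2, 20, n_replicates=2, seed=0)
        assert sweep.n_partitions == 19
        assert sorted(sweep.fits) == list(range(2, 21))

    def test_single_k_sweep(self, rng):
        x, _ = jittered_cloud(rng, unit(rng.normal(size=(5, 10))), reps=20)
        sweep = sweep_k(x, 5, 5, n_replicates=3, seed=0)
        assert sweep.n_partitions == 1

    def test_silhouette_peaks_at_true_k(self, rng):
        gens = np.eye(6)[:4]
        x, _ = jittered_cloud(rng, gens, reps=60, sigma=0.02)
        sweep = sweep_k(x, 2, 6, n_replicates=5, seed=2)
        assert sweep.best_k() == 4


class TestSilhouette:
    def test_antipodal_clusters_near_one(self, rng):
        g = unit(rng.normal(size=(1, 10)))[0]
        x, labels = jittered_cloud(rng, np.vstack([g, -g]), reps=50,
                                   sigma=0.005)
        assert silhouette_score(x, labels + 1) > 0.95

    def test_random_split_of_one_cloud_near_zero(self, rng):
        g = unit(rng.normal(size=(1, 10)))[0]
        x, _ = jittered_cloud(rng, g[None, :], reps=200, sigma=0.02)
        labels = rng.integers(1, 3, size=200)
        assert abs(silhouette_score(x, labels)) < 0.1

    def test_subsample_deterministic_given_seed(self, rng):
        gens = unit(rng.normal(size=(3, 6)))
        x, labels = jittered_cloud(rng, gens, reps=300)
        s1 = silhouette_score(x, labels + 1, subsample_size=100, seed=5)
        s2 = silhouette_score(x, labels + 1, subsample_size=100, seed=5)
        assert s1 == s2

    def test_single_cluster_rejected(self, rng):
        x = unit(rng.normal(size=(20, 5)))
        with pytest.raises(ValueError, match="distinct"):
            silhouette_score(x, np.ones(20, dtype=int))


class TestAssignToCentroids:
    def test_observation_equal_to_centroid(self, rng):
        x = unit(rng.normal(size=(60, 8)))
        cset, _ = fit_kmeans(x, 4, n_replicates=5, seed=1)
        seq = assign_to_centroids(cset.centroids[2][None, :], cset)
        assert seq.labels[0] == 3

    def test_tie_goes_to_lowest_index(self):
        from plstates import CentroidSet

        c = unit(np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0]]))
        cset = CentroidSet(c, 2, np.array([0, 1]), 0.0, 1, 0)
        obs = np.array([[1.0, 0.5, 0.5]])  # equidistant to both centroids
        assert assign_to_centroids(obs, cset).labels[0] == 1

    def test_reassignment_reproduces_fit_labels(self, noisy_scan):
        from plstates import eigenvector_series

        _, ts, _ = noisy_scan
        eigs = eigenvector_series(ts)
        cset, seqs = fit_kmeans(eigs, 4, n_replicates=10, seed=7)
        re_seq = assign_to_centroids(eigs, cset)
        assert np.array_equal(re_seq.labels, seqs[0].labels)

    def test_assignment_is_cosine_voronoi(self, rng):
        x = unit(rng.normal(size=(100, 6)))
        cset, _ = fit_kmeans(x, 3, n_replicates=5, seed=2)
        seq = assign_to_centroids(x, cset)
        sims = x @ cset.centroids.T
        for i in range(100):
            assert sims[i, seq.labels[i] - 1] >= sims[i].max() - 1e-12

    def test_dimension_mismatch_rejected(self, rng):
        x = unit(rng.normal(size=(30, 6)))
        cset, _ = fit_kmeans(x, 3, n_replicates=3, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            assign_to_centroids(unit(rng.normal(size=(5, 9))), cset)

    def test_scan_structure_preserved(self, rng):
        vecs1 = unit(rng.normal(size=(40, 6)))
        vecs2 = unit(rng.normal(size=(25, 6)))
        e1 = LeadingEigSeries(vecs1, np.ones(40), 0.72, scan_id="a")
        e2 = LeadingEigSeries(vecs2, np.ones(25), 0.72, scan_id="b")
        cset, seqs = fit_kmeans([e1, e2], 3, n_replicates=3, seed=0)
        assert [s.scan_id for s in seqs] == ["a", "b"]
        assert [len(s) for s in seqs] == [40, 25]
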