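"""Hilbert phases, coherence matrices and the leading-eigenvector reduction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from plstates import (BOLDTimeSeries, PhaseSeries, compute_phases,
                      eigenvector_series, leading_eigenvector, pattern_matrix,
                      phase_coherence, standardize_sign)

TR = 0.72


def make_ts(data, tr=TR):
    data = np.asarray(data, dtype=float)
    return BOLDTimeSeries(data, tr, [f"r{i}" for i in range(data.shape[0])])


def phases_from(theta_rows):
    theta = np.asarray(theta_rows, dtype=float)
    return PhaseSeries(theta, np.ones_like(theta), TR,
                       [f"r{i}" for i in range(theta.shape[0])])


class TestComputePhases:
    def test_cosine_phase_near_zero_at_peaks(self):
        # f * tr = 0.036 = 9/250, so every 9th peak falls exactly on a
        # sample (t = 250 j); the analytic signal of a cosine is e^{i 2pi f t}
        f = 0.05
        t_axis = np.arange(4096) * TR
        x = np.cos(2 * np.pi * f * t_axis)
        ts = make_ts(np.vstack([x, x + 0.5]))
        ph = compute_phases(ts)
        peaks = 250 * np.arange(1, 16) - 1  # -1 for the boundary trim
        assert np.abs(ph.theta[0, peaks]).max() < 0.05

    def test_trims_one_sample_each_end(self):
        ts = make_ts(np.random.default_rng(0).normal(size=(3, 1200)))
        ph = compute_phases(ts)
        assert ph.theta.shape == (3, 1198)

    def test_identical_signals_identical_phases(self):
        row = np.sin(np.linspace(0, 20, 300))
        ts = make_ts(np.vstack([row, row]))
        ph = compute_phases(ts)
        assert np.array_equal(ph.theta[0], ph.theta[1])

    def test_constant_region_rejected_by_name(self):
        data = np.random.default_rng(1).normal(size=(3, 100))
        data[1] = 7.0
        with pytest.raises(ValueError, match="r1"):
            compute_phases(make_ts(data))


class TestPhaseCoherence:
    def test_aligned_phases_give_all_ones(self):
        ph = phases_from([[0.3], [0.3], [0.3]])
        assert np.allclose(phase_coherence(ph, 0).values, 1.0)

    def test_antiphase_gives_minus_one(self):
        ph = phases_from([[0.0], [np.pi]])
        assert np.allclose(phase_coherence(ph, 0).values,
                           [[1, -1], [-1, 1]])

    def test_quadrature_gives_zero(self):
        ph = phases_from([[0.0], [np.pi / 2]])
        m = phase_coherence(ph, 0).values
        assert abs(m[0, 1]) < 1e-12

    def test_exactly_symmetric_and_unit_diagonal(self, rng):
        ph = phases_from(rng.uniform(-np.pi, np.pi, size=(6, 4)))
        m = phase_coherence(ph, 2).values
        assert np.array_equal(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_positive_semidefinite(self, rng):
        ph = phases_from(rng.uniform(-np.pi, np.pi, size=(8, 3)))
        m = phase_coherence(ph, 1).values
        assert np.linalg.eigvalsh(m).min() >= -1e-9

    def test_out_of_range_sample(self):
        ph = phases_from([[0.0, 1.0], [0.5, 0.2]])
        with pytest.raises(IndexError):
            phase_coherence(ph, 5)


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        n = 6
        v, lam = leading_eigenvector(np.ones((n, n)))
        assert np.isclose(lam, n)
        assert np.allclose(v, -np.ones(n) / np.sqrt(n))

    def test_two_community_block_pattern(self):
        ph = phases_from([[0.0], [0.0], [np.pi], [np.pi]])
        v, lam = leading_eigenvector(phase_coherence(ph, 0))
        assert np.isclose(lam, 4.0)
        assert np.allclose(np.abs(v), 0.5)
        # minority/majority tie at 2 vs 2: convention fixes overall sign
        assert v.sum() <= 1e-12

    def test_matches_full_spectrum_oracle(self, rng):
        """Returned pair equals the dominant pair of a brute-force full
        eigendecomposition, and maximizes the Rayleigh quotient."""
        for _ in range(50):
            n = rng.integers(2, 11)
            a = rng.normal(size=(n, n))
            m = (a + a.T) / 2
            v, lam = leading_eigenvector(m)
            w, vecs = np.linalg.eigh(m)  # independent full-spectrum oracle
            assert abs(lam - w.max()) < 1e-8
            assert np.isclose(abs(v @ vecs[:, -1]), 1.0, atol=1e-6)
            for j in range(n - 1):
                assert v @ m @ v >= vecs[:, j] @ m @ vecs[:, j] - 1e-8

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            leading_eigenvector(np.array([[1.0, 2.0], [0.0, 1.0]]))

    @given(hnp.arrays(np.float64, st.integers(2, 8),
                      elements=st.floats(-5, 5)))
    def test_sign_convention_idempotent(self, v):
        once = standardize_sign(v)
        assert np.array_equal(standardize_sign(once), once)
        assert once.sum() <= 1e-12 or np.all(v == 0)


class TestEigenvectorSeries:
    def test_1200_samples_give_1198_rows(self):
        ts = make_ts(np.random.default_rng(2).normal(size=(5, 1200)))
        eigs = eigenvector_series(ts)
        assert eigs.vectors.shape == (1198, 5)
        assert np.allclose(np.linalg.norm(eigs.vectors, axis=1), 1.0,
                           atol=1e-9)

    def test_zero_noise_rows_match_planted_patterns(self, noiseless_eigs):
        """Away from state transitions (where the Hilbert transform smears
        phases across neighbouring samples) every zero-noise eigenvector
        carries the sign pattern of the state in force at that sample."""
        eigs, truth = noiseless_eigs
        seq = truth.state_sequence[1:-1]  # align with the boundary trim
        change = np.flatnonzero(np.diff(seq) != 0)
        edges = np.concatenate((change, change + 1))
        dist = np.abs(np.arange(seq.size)[:, None] - edges[None, :]).min(1)
        interior = np.flatnonzero(dist >= 2)
        interior = interior[(interior > 2) & (interior < seq.size - 3)]
        assert interior.size > 30
        signs = np.sign(eigs.vectors[interior])
        expected = truth.true_centroid_signs[seq[interior] - 1]
        assert np.array_equal(signs, expected)

    def test_eigenvalue_bounded_by_trace(self, noiseless_eigs):
        # dPC is PSD with unit diagonal: leading eigenvalue lies in [1, N]
        eigs, _ = noiseless_eigs
        assert np.all(eigs.eigenvalues <= eigs.n_regions + 1e-9)
        assert np.all(eigs.eigenvalues >= 1 - 1e-9)


class TestPatternMatrix:
    def test_basis_vector(self):
        assert np.allclose(pattern_matrix(np.array([1.0, 0.0])),
                           [[1, 0], [0, 0]])

    def test_sign_cancels(self):
        v = -np.ones(2) / np.sqrt(2)
        assert np.allclose(pattern_matrix(v), 0.5)

    def test_trace_one_for_random_unit_vectors(self, rng):
        for _ in range(10):
            v = rng.normal(size=7)
            v /= np.linalg.norm(v)
            p = pattern_matrix(v)
            assert np.isclose(np.trace(p), 1.0)
            assert np.allclose(p, p.T)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            pattern_matrix(np.array([1.0, 1.0]))
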