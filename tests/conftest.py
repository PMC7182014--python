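import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from plstates import (SyntheticSpec, eigenvector_series, simulate_bold,
                      simulate_state_sequence)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Small noise-free generator spec: exact blockwise +/-1 coherence."""
    return SyntheticSpec(
        n_regions=12, n_states=3, n_samples=400,
        phase_jitter_sd=0.0, amplitude_noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_scan(noiseless_spec):
    seq = simulate_state_sequence(noiseless_spec)
    ts, truth = simulate_bold(noiseless_spec, seq)
    return ts, truth


@pytest.fixture(scope="session")
def noiseless_eigs(noiseless_scan):
    ts, truth = noiseless_scan
    return eigenvector_series(ts), truth


@pytest.fixture(scope="session")
def noisy_scan():
    spec = SyntheticSpec(n_regions=20, n_states=4, n_samples=600,
                         phase_jitter_sd=0.3, amplitude_noise_sd=0.2, seed=11)
    seq = simulate_state_sequence(spec)
    ts, truth = simulate_bold(spec, seq)
    return spec, ts, truth


def unit_rows(x):
    return x / np.linalg.norm(x, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def match_centroids():
    """Greedy one-to-one matching of centroids to reference patterns by
    absolute cosine similarity; returns the per-centroid best |cos|."""

    def _match(centroids, patterns):
        sims = np.abs(unit_rows(centroids) @ unit_rows(patterns).T)
        k = sims.shape[0]
        out = np.empty(k)
        taken = set()
        for _ in range(k):
            a, b = np.unravel_index(
                np.argmax(np.where(
                    np.isneginf(sims), -np.inf, sims)), sims.shape)
            out[a] = sims[a, b]
            sims[a, :] = -np.inf
            sims[:, b] = -np.inf
            taken.add((a, b))
        return out

    return _match
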