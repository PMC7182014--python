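"""Synthetic BOLD-like signals with planted, Markov-switching phase-locking.

The generator emulates the key structure of the empirical observable: N
regional oscillations around a carrier frequency whose instantaneous phase
configuration switches between k planted patterns. Pattern 1 is the global
in-phase state (all regions aligned); each of the remaining k − 1 patterns
phase-shifts a designated minority community of regions by π. The pattern in
force at each TR follows a homogeneous Markov chain with known transition
matrix, so every downstream estimator (occupancy, dwell time, transition
matrix, centroid recovery) can be checked against exported ground truth.

Noise enters in two places: independent Gaussian jitter on each region's
phase argument (degrades but does not bias the eigenvector sign pattern) and
additive Gaussian amplitude noise on the signal itself. Hemodynamic
convolution, spatially correlated noise and subject-level heterogeneity
beyond seed changes are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import BOLDTimeSeries, nyquist_frequency

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "default_transition_matrix",
    "default_communities",
    "stationary_distribution",
    "simulate_state_sequence",
    "simulate_bold",
    "simulate_dataset",
    "write_dataset",
]


def default_transition_matrix(n_states: int = 5) -> np.ndarray:
    """Row-stochastic chain with a sticky global state and return asymmetry.

    State 1 self-transitions with probability 0.77 and distributes the rest
    uniformly; the other ("ghost") states self-transition at 0.45 (close to
    chance), return to state 1 at 0.24 and spread the remaining mass over the
    other ghost states. Flow balance then puts the stationary occupancy of
    the global state at 0.24 / (0.23 + 0.24) ≈ 0.51, and the chain shows the
    pronounced asymmetry W(α→1) ≫ W(1→α) of a baseline synchronous state
    visited by brief excursions.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    w = np.zeros((n_states, n_states))
    w[0, 0] = 0.77
    w[0, 1:] = 0.23 / (n_states - 1)
    for a in range(1, n_states):
        w[a, a] = 0.45
        w[a, 0] = 0.24
        others = [b for b in range(1, n_states) if b != a]
        if others:
            w[a, others] = 0.31 / len(others)
        else:
            w[a, 0] += 0.31
    return w


def default_communities(n_regions: int, n_states: int) -> list[list[int]]:
    """Disjoint contiguous minority communities, one per non-global state.

    State 1 gets the empty community (global in-phase pattern); states
    2..k shift blocks of ``n_regions // n_states`` regions, each strictly
    smaller than half the regions so the planted community is the
    eigenvector minority.
    """
    block = max(1, min(n_regions // n_states, (n_regions - 1) // 2))
    comms: list[list[int]] = [[]]
    for a in range(1, n_states):
        start = (a - 1) * block
        comms.append(list(range(start, start + block)))
    if comms[-1] and comms[-1][-1] >= n_regions:
        raise ValueError("too many states for the requested region count")
    return comms


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic scan.

    Defaults mirror the empirical acquisition geometry at desk scale:
    N = 30 regions, k = 5 states, T = 1198 samples at TR = 0.72 s, a 0.05 Hz
    carrier in the canonical resting-state band, phase jitter 0.3 rad and
    additive amplitude noise with SD 0.2 (signal amplitude 1).
    """

    n_regions: int = 30
    n_states: int = 5
    communities: tuple[tuple[int, ...], ...] | None = None
    transition_matrix: np.ndarray | None = None
    carrier_freq: float = 0.05
    phase_jitter_sd: float = 0.3
    amplitude_noise_sd: float = 0.2
    tr: float = 0.72
    n_samples: int = 1198
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_states < 1:
            raise ValueError("need at least 1 state")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.carrier_freq < nyquist_frequency(self.tr):
            raise ValueError(
                "carrier frequency must lie strictly below Nyquist "
                f"({nyquist_frequency(self.tr):.4g} Hz)"
            )
        if self.phase_jitter_sd < 0 or self.amplitude_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")

        comms = self.communities
        if comms is None:
            comms = default_communities(self.n_regions, self.n_states)
        comms = tuple(tuple(int(i) for i in c) for c in comms)
        if len(comms) != self.n_states:
            raise ValueError("one community per state is required")
        if comms[0] != ():
            raise ValueError("state 1 must have the empty community")
        for c in comms:
            if len(set(c)) != len(c):
                raise ValueError("community members must be unique")
            if any(i < 0 or i >= self.n_regions for i in c):
                raise ValueError("community index out of range")
            if len(c) >= self.n_regions / 2:
                raise ValueError(
                    "communities must contain fewer than N/2 regions"
                )
        object.__setattr__(self, "communities", comms)

        w = self.transition_matrix
        if w is None:
            w = default_transition_matrix(self.n_states)
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_states, self.n_states):
            raise ValueError(f"transition matrix must be {self.n_states} x "
                             f"{self.n_states}, got {w.shape}")
        if (w < 0).any() or np.abs(w.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("transition matrix must be row-stochastic")
        w.setflags(write=False)
        object.__setattr__(self, "transition_matrix", w)

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Exported ground truth for one simulated scan."""

    state_sequence: np.ndarray       # (T,) labels in 1..k
    true_centroid_signs: np.ndarray  # (k, N) of ±1 (+1 on the community)
    true_occupancy: np.ndarray       # empirical occupancy of the sequence
    true_transition_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        self.true_centroid_signs = np.asarray(self.true_centroid_signs, float)
        self.true_occupancy = np.asarray(self.true_occupancy, dtype=float)
        self.true_transition_matrix = np.asarray(
            self.true_transition_matrix, dtype=float)
        if abs(self.true_occupancy.sum() - 1.0) > 1e-9:
            raise ValueError("true occupancy must sum to 1")


def stationary_distribution(w: np.ndarray) -> np.ndarray:
    """Stationary distribution π solving πW = π, via the eigenproblem of Wᵀ."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("transition matrix must be square")
    vals, vecs = np.linalg.eig(w.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _rng_for(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # one documented RNG root per spec; streams 0 (chain) and 1 (signal)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(stream,))
    )


def simulate_state_sequence(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample a length-T label sequence (1..k) from the planted Markov chain.

    The chain starts at its stationary distribution so finite-T occupancy
    estimates are unbiased. Reproducible given ``spec.seed``.
    """
    if rng is None:
        rng = _rng_for(spec, 0)
    w = spec.transition_matrix
    k, t_total = spec.n_states, spec.n_samples
    pi = stationary_distribution(w)
    cum_w = np.cumsum(w, axis=1)
    seq = np.empty(t_total, dtype=int)
    seq[0] = rng.choice(k, p=pi)
    draws = rng.random(t_total - 1)
    for t in range(1, t_total):
        seq[t] = np.searchsorted(cum_w[seq[t - 1]], draws[t - 1], side="right")
    return seq + 1


def simulate_bold(
    spec: SyntheticSpec,
    state_sequence: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[BOLDTimeSeries, SyntheticTruth]:
    """Render a label sequence into an N × T BOLD-like signal plus truth.

    Region n at sample t carries
    ``cos(2π f t·tr + π·[n ∈ community(state(t))] + jitter) + noise``.
    """
    if rng is None:
        rng = _rng_for(spec, 1)
    seq = np.asarray(state_sequence, dtype=int)
    if seq.ndim != 1 or seq.shape[0] != spec.n_samples:
        raise ValueError("state sequence length must equal n_samples")
    if seq.min(initial=1) < 1 or seq.max(initial=1) > spec.n_states:
        raise ValueError("state labels must lie in 1..k")
    n, t_total, k = spec.n_regions, spec.n_samples, spec.n_states

    # (k, N) phase offsets: pi on each state's community
    offsets = np.zeros((k, n))
    signs = -np.ones((k, n))
    for a, comm in enumerate(spec.communities):
        idx = np.asarray(comm, dtype=int)
        if idx.size:
            offsets[a, idx] = np.pi
            signs[a, idx] = 1.0

    t_idx = np.arange(t_total)
    base = 2 * np.pi * spec.carrier_freq * spec.tr * t_idx  # (T,)
    phase = base[None, :] + offsets[seq - 1].T               # (N, T)
    if spec.phase_jitter_sd > 0:
        phase = phase + rng.normal(0.0, spec.phase_jitter_sd, size=(n, t_total))
    data = np.cos(phase)
    if spec.amplitude_noise_sd > 0:
        data = data + rng.normal(0.0, spec.amplitude_noise_sd,
                                 size=(n, t_total))

    occupancy = np.bincount(seq - 1, minlength=k) / t_total
    truth = SyntheticTruth(seq, signs, occupancy, spec.transition_matrix)
    ts = BOLDTimeSeries(
        data, spec.tr, [f"R{i:03d}" for i in range(n)],
        scan_id=f"synthetic-seed{spec.seed}", session_tag="",
        meta={"synthetic": True, "seed": spec.seed},
    )
    return ts, truth


def _scan_seed(base_seed: int, subject: int, session: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed,
                                spawn_key=(subject, session))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_dataset(
    spec: SyntheticSpec,
    n_subjects: int,
    sessions: tuple[str, ...] = ("LR", "RL"),
) -> dict[str, list[tuple[BOLDTimeSeries, SyntheticTruth]]]:
    """Simulate a multi-subject, multi-session cohort.

    Every scan shares the planted patterns and transition matrix but uses its
    own derived seed, so sessions of the same subject are independent
    realizations (no subject-level effect is modelled).
    """
    out: dict[str, list[tuple[BOLDTimeSeries, SyntheticTruth]]] = {}
    for s_i, sess in enumerate(sessions):
        scans = []
        for subj in range(n_subjects):
            scan_spec = spec.replace(seed=_scan_seed(spec.seed, subj, s_i))
            seq = simulate_state_sequence(scan_spec)
            ts, truth = simulate_bold(scan_spec, seq)
            ts.scan_id = f"sub{subj:03d}"
            ts.session_tag = sess
            scans.append((ts, truth))
        out[sess] = scans
    return out


def write_dataset(
    dataset: dict[str, list[tuple[BOLDTimeSeries, SyntheticTruth]]],
    out_dir,
    spec: SyntheticSpec | None = None,
) -> None:
    """Write signals as TSV (regions × samples) and truth as JSON."""
    from . import io as plio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sess, scans in dataset.items():
        for ts, truth in scans:
            stem = f"{ts.scan_id}_{sess}"
            plio.write_bold(ts, out_dir / f"{stem}.tsv")
            payload = {
                "state_sequence": truth.state_sequence.tolist(),
                "true_centroid_signs": truth.true_centroid_signs.tolist(),
                "true_occupancy": truth.true_occupancy.tolist(),
                "true_transition_matrix":
                    truth.true_transition_matrix.tolist(),
            }
            (out_dir / f"{stem}_truth.json").write_text(
                json.dumps(payload))
    if spec is not None:
        meta = {
            "n_regions": spec.n_regions,
            "n_states": spec.n_states,
            "communities": [list(c) for c in spec.communities],
            "transition_matrix": spec.transition_matrix.tolist(),
            "carrier_freq": spec.carrier_freq,
            "phase_jitter_sd": spec.phase_jitter_sd,
            "amplitude_noise_sd": spec.amplitude_noise_sd,
            "tr": spec.tr,
            "n_samples": spec.n_samples,
            "seed": spec.seed,
        }
        (out_dir / "spec.json").write_text(json.dumps(meta, indent=2))
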