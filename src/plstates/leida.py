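"""Leading-eigenvector dynamics of instantaneous BOLD phase coherence.

Each region's demeaned signal is extended to its analytic form via the
Hilbert transform, giving an instantaneous phase θ(n, t). The pairwise phase
coherence at time t is cos(θ(n, t) − θ(m, t)), an N × N Gram matrix of unit
phasors, and its dominant (leading) eigenvector V1(t) summarizes the
whole-brain phase-locking pattern at that TR in a single 1 × N vector. The
first and last samples are dropped to exclude Hilbert boundary artifacts.

Sign convention: eigenvectors are defined up to sign, so every V1 is flipped
if necessary so that its element-wise mean is ≤ 0. Under this convention the
regions whose phase is shifted away from the dominant orientation — the
minority community that defines a phase-locking state — carry the positive
entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import BOLDTimeSeries

__all__ = [
    "PhaseSeries",
    "CoherenceMatrix",
    "LeadingEigSeries",
    "compute_phases",
    "phase_coherence",
    "leading_eigenvector",
    "eigenvector_series",
    "pattern_matrix",
    "standardize_sign",
]

#: eigenvalue gap below which the leading eigenvector is reported as
#: near-degenerate (the deterministic solver output is kept either way)
DEGENERACY_GAP = 1e-10


@dataclass
class PhaseSeries:
    """Instantaneous phase and amplitude of the analytic BOLD signal."""

    theta: np.ndarray      # (N, T') phases in (-pi, pi]
    amplitude: np.ndarray  # (N, T') non-negative envelope
    tr: float
    region_labels: list[str]
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.theta.shape != self.amplitude.shape:
            raise ValueError("theta and amplitude shapes differ")
        if np.abs(self.theta).max(initial=0.0) > np.pi + 1e-12:
            raise ValueError("phases must lie in (-pi, pi]")


@dataclass
class CoherenceMatrix:
    """Instantaneous N × N phase-coherence matrix at one retained sample."""

    values: np.ndarray
    t_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coherence matrix must be square")


@dataclass
class LeadingEigSeries:
    """Unit-norm leading eigenvectors of the coherence matrices over time.

    Row t' corresponds to original sample t' + 1 (one sample trimmed at each
    end of the scan).
    """

    vectors: np.ndarray      # (T', N)
    eigenvalues: np.ndarray  # (T',)
    tr: float
    scan_id: str = ""
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (samples x regions)")
        if self.eigenvalues.shape[0] != self.vectors.shape[0]:
            raise ValueError("one eigenvalue per retained sample is required")

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_regions(self) -> int:
        return self.vectors.shape[1]


def standardize_sign(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its element-wise mean is ≤ 0 (idempotent).

    If the mean is exactly zero the first nonzero element is made negative.
    """
    v = np.asarray(v, dtype=float)
    s = v.sum()
    if s > 0:
        return -v
    if s == 0:
        nz = np.flatnonzero(v)
        if nz.size and v[nz[0]] > 0:
            return -v
    return v


def compute_phases(ts: BOLDTimeSeries) -> PhaseSeries:
    """Hilbert phases and amplitudes of the demeaned region signals.

    Each region is demeaned before the transform (a nonzero mean biases the
    analytic-signal phase toward 0). The first and last samples are dropped,
    so the output has T − 2 samples.
    """
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    flat = np.flatnonzero(np.ptp(x, axis=1) == 0)
    if flat.size:
        names = ", ".join(ts.region_labels[i] for i in flat[:5])
        raise ValueError(f"constant signal in region(s): {names}")
    analytic = hilbert(x, axis=1)
    theta = np.angle(analytic[:, 1:-1])
    amplitude = np.abs(analytic[:, 1:-1])
    return PhaseSeries(theta, amplitude, ts.tr, list(ts.region_labels),
                       scan_id=ts.scan_id)


def phase_coherence(phases: PhaseSeries, t: int) -> CoherenceMatrix:
    """Pairwise phase-coherence matrix cos(θn − θm) at retained sample ``t``.

    Computed as cosθ·cosθᵀ + sinθ·sinθᵀ, which is symmetric by construction
    and positive semidefinite (it is the Gram matrix of the unit phasors
    (cos θ, sin θ) per region).
    """
    n_t = phases.theta.shape[1]
    if not (-n_t <= t < n_t):
        raise IndexError(f"sample index {t} out of range for {n_t} samples")
    th = phases.theta[:, t]
    c, s = np.cos(th), np.sin(th)
    return CoherenceMatrix(np.outer(c, c) + np.outer(s, s), t_index=t % n_t)


def _leading_from_symmetric(m: np.ndarray) -> tuple[np.ndarray, float]:
    # full symmetric eigendecomposition: exactness over speed at N <= 512
    w, v = np.linalg.eigh(m)
    if m.shape[0] > 1 and w[-1] - w[-2] < DEGENERACY_GAP:
        warnings.warn(
            "near-degenerate leading eigenvalue "
            f"(gap {w[-1] - w[-2]:.2e}); deterministic solver vector kept",
            RuntimeWarning,
            stacklevel=3,
        )
    return standardize_sign(v[:, -1]), float(w[-1])


def leading_eigenvector(m) -> tuple[np.ndarray, float]:
    """Unit eigenvector of the algebraically largest eigenvalue.

    Accepts a :class:`CoherenceMatrix` or a plain symmetric array. The
    returned vector follows the mean ≤ 0 sign convention.
    """
    values = m.values if isinstance(m, CoherenceMatrix) else np.asarray(m, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("input matrix is not symmetric")
    return _leading_from_symmetric(values)


def eigenvector_series(ts: BOLDTimeSeries) -> LeadingEigSeries:
    """Leading-eigenvector trajectory V1(t) over all retained samples."""
    phases = compute_phases(ts)
    ct = np.cos(phases.theta)
    st = np.sin(phases.theta)
    n, t_ret = phases.theta.shape
    vectors = np.empty((t_ret, n))
    eigenvalues = np.empty(t_ret)
    for t in range(t_ret):
        m = np.outer(ct[:, t], ct[:, t]) + np.outer(st[:, t], st[:, t])
        vectors[t], eigenvalues[t] = _leading_from_symmetric(m)
    return LeadingEigSeries(vectors, eigenvalues, ts.tr, scan_id=ts.scan_id,
                            region_labels=list(ts.region_labels))


def pattern_matrix(v: np.ndarray) -> np.ndarray:
    """Rank-1 phase-locking pattern v·vᵀ of a unit vector (trace 1)."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    nrm = np.linalg.norm(v)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        raise ValueError(f"expected a unit vector, norm is {nrm:.6g}")
    return np.outer(v, v)
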