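"""Partition of leading-eigenvector phase space into k phase-locking states.

The pooled leading eigenvectors of a discovery session are clustered with
k-means under the cosine distance d(x, c) = 1 − x·c / (|x||c|), repeated from
many random initializations, keeping the replicate with minimal total
within-cluster cosine distance. States are re-indexed by descending pooled
fractional occupancy, so state 1 is always the most frequent pattern (the
globally phase-locked state in practice). Held-out (validation) sessions are
projected onto the fitted centroids by nearest-centroid assignment without
any refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score as _sk_silhouette

from .leida import LeadingEigSeries, standardize_sign

__all__ = [
    "CentroidSet",
    "StateSequence",
    "fit_kmeans",
    "sweep_k",
    "SweepResult",
    "silhouette_score",
    "assign_to_centroids",
]


@dataclass
class CentroidSet:
    """k unit-norm state centroids V_c, ordered by descending occupancy."""

    centroids: np.ndarray  # (k, N)
    k: int
    ordering: np.ndarray   # permutation applied to the raw fit labels
    fit_inertia: float     # total within-cluster cosine distance
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.ordering = np.asarray(self.ordering, dtype=int)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        if sorted(self.ordering.tolist()) != list(range(self.k)):
            raise ValueError("ordering must be a permutation of 0..k-1")

    @property
    def n_regions(self) -> int:
        return self.centroids.shape[1]


@dataclass
class StateSequence:
    """Trajectory of 1-based state labels over one scan's retained TRs."""

    labels: np.ndarray
    scan_id: str
    k: int
    tr: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D vector")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")

    def __len__(self) -> int:
        return self.labels.size


def _pool(eigs) -> tuple[np.ndarray, list[tuple[str, int, float]]]:
    """Stack one or more LeadingEigSeries; remember per-scan extents."""
    if isinstance(eigs, LeadingEigSeries):
        eigs = [eigs]
    if isinstance(eigs, np.ndarray):
        x = np.asarray(eigs, dtype=float)
        return x, [("pooled", x.shape[0], np.nan)]
    mats, scans = [], []
    for e in eigs:
        mats.append(e.vectors)
        scans.append((e.scan_id, e.vectors.shape[0], e.tr))
    if not mats:
        raise ValueError("no eigenvector series supplied")
    return np.vstack(mats), scans


def _unit_rows(x: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(x, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return x / nrm


def _kmeans_cosine_once(
    x_unit: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """One seeded cosine k-means replicate on unit-norm observations."""
    n = x_unit.shape[0]
    centers = x_unit[rng.choice(n, size=k, replace=False)].copy()
    labels = None
    for _ in range(max_iter):
        sims = x_unit @ centers.T
        new_labels = np.argmax(sims, axis=1)  # ties -> lowest index
        # re-seed empty clusters with the worst-fitting observation
        counts = np.bincount(new_labels, minlength=k)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            assigned = sims[np.arange(n), new_labels].copy()
            for j in empty:
                far = int(np.argmin(assigned))
                new_labels[far] = j
                assigned[far] = np.inf
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = x_unit[labels == j]
            m = members.mean(axis=0)
            nrm = np.linalg.norm(m)
            centers[j] = m / nrm if nrm > 0 else members[0]
    # final assignment against the final centroids, so that re-assigning the
    # training data through assign_to_centroids reproduces the fit labels
    sims = x_unit @ centers.T
    labels = np.argmax(sims, axis=1)
    inertia = float(np.sum(1.0 - sims[np.arange(n), labels]))
    return labels, centers, inertia


def fit_kmeans(
    eigs,
    k: int,
    n_replicates: int = 100,
    seed: int = 0,
    max_iter: int = 300,
) -> tuple[CentroidSet, list[StateSequence]]:
    """Cosine k-means over pooled eigenvectors, best of ``n_replicates``.

    Each replicate initializes the centroids on k distinct observations
    drawn from a seeded stream; the replicate with minimal total
    within-cluster cosine distance wins. The returned centroids are
    unit-norm, sign-standardized (element-wise mean ≤ 0) and re-indexed by
    descending pooled occupancy; labels are 1-based.
    """
    x, scans = _pool(eigs)
    n = x.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must lie in [2, n_observations={n}]")
    x_unit = _unit_rows(x)
    root = np.random.SeedSequence(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for child in root.spawn(n_replicates):
        rng = np.random.default_rng(child)
        labels, centers, inertia = _kmeans_cosine_once(x_unit, k, rng, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    labels, centers, inertia = best

    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    centers = np.vstack([standardize_sign(c) for c in centers[order]])
    centers = _unit_rows(centers)
    labels = remap[labels] + 1

    cset = CentroidSet(centers, k, order, inertia, n_replicates, seed)
    sequences, start = [], 0
    for scan_id, length, tr in scans:
        sequences.append(StateSequence(labels[start:start + length],
                                       scan_id, k, tr=tr))
        start += length
    return cset, sequences


@dataclass
class SweepResult:
    """Per-k fits and a summary table from a k sweep."""

    fits: dict[int, tuple[CentroidSet, list[StateSequence]]]
    table: pd.DataFrame  # columns: k, silhouette, inertia

    @property
    def n_partitions(self) -> int:
        return len(self.fits)

    def best_k(self) -> int:
        return int(self.table.loc[self.table["silhouette"].idxmax(), "k"])


def sweep_k(
    eigs,
    k_min: int = 2,
    k_max: int = 20,
    n_replicates: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    silhouette_subsample: int = 20000,
) -> SweepResult:
    """Fit one partition per k in [k_min, k_max] and score each by silhouette."""
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    fits = {}
    rows = []
    for k in range(k_min, k_max + 1):
        cset, seqs = fit_kmeans(eigs, k, n_replicates=n_replicates,
                                seed=seed, max_iter=max_iter)
        sil = silhouette_score(eigs, seqs,
                               subsample_size=silhouette_subsample, seed=seed)
        fits[k] = (cset, seqs)
        rows.append({"k": k, "silhouette": sil, "inertia": cset.fit_inertia})
    return SweepResult(fits, pd.DataFrame(rows))


def silhouette_score(
    eigs,
    labels,
    subsample_size: int = 20000,
    seed: int = 0,
) -> float:
    """Mean silhouette under cosine distance, on a seeded uniform subsample.

    The full pairwise distance matrix is quadratic in the pooled observation
    count, so when that count exceeds ``subsample_size`` the score is
    computed on a seeded uniform subsample (resampled, up to a bound, if the
    draw happens to contain a single cluster).
    """
    x, _ = _pool(eigs)
    if isinstance(labels, StateSequence):
        labels = [labels]
    if isinstance(labels, (list, tuple)):
        y = np.concatenate([s.labels for s in labels])
    else:
        y = np.asarray(labels, dtype=int)
    if y.shape[0] != x.shape[0]:
        raise ValueError("one label per observation is required")
    if np.unique(y).size < 2:
        raise ValueError("silhouette requires at least 2 distinct labels")
    n = x.shape[0]
    if n > subsample_size:
        rng = np.random.default_rng(seed)
        for _ in range(100):
            idx = rng.choice(n, size=subsample_size, replace=False)
            if np.unique(y[idx]).size >= 2:
                break
        else:  # pragma: no cover - pathological label imbalance
            raise ValueError("could not draw a subsample with 2 clusters")
        x, y = x[idx], y[idx]
    return float(_sk_silhouette(x, y, metric="cosine"))


def assign_to_centroids(eigs, centroid_set: CentroidSet):
    """Label observations by their nearest centroid under cosine distance.

    Ties go to the lowest centroid index. Used verbatim for held-out
    sessions — the centroids are never refit. Returns one StateSequence per
    input series (or a single one for an array / single-series input).
    """
    single = isinstance(eigs, (LeadingEigSeries, np.ndarray))
    x, scans = _pool(eigs)
    if x.shape[1] != centroid_set.n_regions:
        raise ValueError(
            f"observation dimension {x.shape[1]} does not match centroid "
            f"dimension {centroid_set.n_regions}"
        )
    sims = _unit_rows(x) @ _unit_rows(centroid_set.centroids).T
    labels = np.argmax(sims, axis=1) + 1
    sequences, start = [], 0
    for scan_id, length, tr in scans:
        sequences.append(StateSequence(labels[start:start + length],
                                       scan_id, centroid_set.k, tr=tr))
        start += length
    return sequences[0] if single else sequences
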