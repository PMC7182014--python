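"""Overlap of state centroids with reference intrinsic functional networks.

A reference atlas of M non-overlapping networks and a parcellation of N
regions, both defined on the same voxel grid, are reduced to an M × N matrix
of voxel proportions: entry (m, n) is the fraction of parcel n's voxels that
fall inside network m. Each state centroid is rectified (negative entries set
to zero, keeping only the community whose phase is shifted away from the
dominant orientation under the mean ≤ 0 sign convention) and correlated with
each reference row by Pearson's r over the N regions. Significance uses the
two-sided t transform of r with N − 2 degrees of freedom, Bonferroni
corrected either per partition (α/k) or per state (α/M); spatial
autocorrelation between parcels is not corrected for, so p-values are
nominal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import CentroidSet

__all__ = [
    "ReferenceNetworks",
    "OverlapResult",
    "reference_from_volumes",
    "centroid_network_overlap",
]


@dataclass
class ReferenceNetworks:
    """M reference networks expressed as voxel proportions over N regions."""

    matrix: np.ndarray  # (M, N), entries in [0, 1], column sums <= 1
    network_names: list[str]
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m, n = self.matrix.shape
        if len(self.network_names) != m or len(self.region_labels) != n:
            raise ValueError("name lists must match the matrix shape")
        if (self.matrix < -1e-12).any() or (self.matrix > 1 + 1e-12).any():
            raise ValueError("proportions must lie in [0, 1]")
        if (self.matrix.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("per-region proportions must sum to at most 1")


@dataclass
class OverlapResult:
    r_matrix: np.ndarray      # (k, M)
    p_matrix: np.ndarray      # (k, M)
    best_match: list[str]     # per state; "none" when nothing survives
    alpha_corrected: float


def _as_label_array(vol) -> np.ndarray:
    if hasattr(vol, "get_fdata"):  # nibabel image
        return np.rint(np.asarray(vol.get_fdata())).astype(int)
    return np.asarray(vol).astype(int)


def reference_from_volumes(
    network_labels,
    parcellation_labels,
    region_order=None,
    network_order=None,
    network_names=None,
    region_labels=None,
) -> ReferenceNetworks:
    """Build the M × N proportion matrix from two integer label volumes.

    Both volumes must share the grid; label 0 means unassigned in both.
    Unassigned voxels inside a parcel still count in the denominator, so a
    parcel lying entirely outside every network yields an all-zero column
    (with a warning). Accepts plain integer arrays or nibabel images.
    """
    net = _as_label_array(network_labels)
    parc = _as_label_array(parcellation_labels)
    if net.shape != parc.shape:
        raise ValueError(
            f"volume grids differ: {net.shape} vs {parc.shape}"
        )
    if (hasattr(network_labels, "affine")
            and hasattr(parcellation_labels, "affine")
            and not np.allclose(network_labels.affine,
                                parcellation_labels.affine, atol=1e-4)):
        raise ValueError("volumes are not in the same space (affines differ)")
    net = net.reshape(-1)
    parc = parc.reshape(-1)
    if region_order is None:
        region_order = [int(v) for v in np.unique(parc) if v != 0]
    if network_order is None:
        network_order = [int(v) for v in np.unique(net) if v != 0]
    m = len(network_order)
    n = len(region_order)
    matrix = np.zeros((m, n))
    for j, parcel in enumerate(region_order):
        mask = parc == parcel
        total = int(mask.sum())
        if total == 0:
            raise ValueError(f"parcel {parcel!r} has no voxels")
        for i, network in enumerate(network_order):
            matrix[i, j] = np.count_nonzero(net[mask] == network) / total
        if matrix[:, j].sum() == 0:
            warnings.warn(
                f"parcel {parcel!r} has no voxels inside any reference "
                "network", RuntimeWarning, stacklevel=2,
            )
    if network_names is None:
        network_names = [f"net{v}" for v in network_order]
    if region_labels is None:
        region_labels = [str(v) for v in region_order]
    return ReferenceNetworks(matrix, list(network_names), list(region_labels))


def centroid_network_overlap(
    centroids,
    ref: ReferenceNetworks,
    alpha: float = 0.05,
    correction: str = "per_partition",
) -> OverlapResult:
    """Pearson overlap of rectified centroids with each reference network.

    ``correction`` selects the Bonferroni denominator: ``"per_partition"``
    uses α/k (one test family per clustering solution), ``"per_state"`` uses
    α/M (one family per state across the M networks). A centroid that is
    constant after rectification (e.g. the all-aligned global state, whose
    entries are all negative) has no defined correlation and is reported
    with r = NaN, p = 1.
    """
    if isinstance(centroids, CentroidSet):
        if (centroids.n_regions != len(ref.region_labels)):
            raise ValueError("centroid regions do not match reference regions")
        c = centroids.centroids
    else:
        c = np.asarray(centroids, dtype=float)
        if c.ndim != 2 or c.shape[1] != len(ref.region_labels):
            raise ValueError("centroid regions do not match reference regions")
    k, n = c.shape
    m = ref.matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 regions for a correlation test")
    if correction == "per_partition":
        alpha_corr = alpha / k
    elif correction == "per_state":
        alpha_corr = alpha / m
    else:
        raise ValueError("correction must be 'per_partition' or 'per_state'")

    rect = np.clip(c, 0.0, None)
    r = np.full((k, m), np.nan)
    p = np.ones((k, m))
    for a in range(k):
        if rect[a].std() == 0:
            continue
        for j in range(m):
            if ref.matrix[j].std() == 0:
                continue
            res = stats.pearsonr(rect[a], ref.matrix[j])
            r[a, j] = res.statistic
            p[a, j] = res.pvalue

    best = []
    for a in range(k):
        significant = np.flatnonzero(p[a] < alpha_corr)
        if significant.size == 0:
            best.append("none")
        else:
            # most significant network; tie on p broken by larger |r|
            order = sorted(significant,
                           key=lambda j: (p[a, j], -abs(r[a, j])))
            best.append(ref.network_names[order[0]])
    return OverlapResult(r, p, best, alpha_corr)
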