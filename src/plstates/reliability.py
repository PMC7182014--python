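"""Test–retest reliability of state metrics via intra-class correlation.

For a metric measured once in each of two same-day sessions for S subjects,

    ICC = (MSE_b - MSE_w) / (MSE_b + MSE_w),

with the one-way random-effects decomposition at J = 2 repeats:

    MSE_b = 2 * sum_s (x̄_s - x̄)^2 / (S - 1)      (between-subject)
    MSE_w = sum_s sum_j (x_sj - x̄_s)^2 / S        (within-subject)

which makes the formula identical to the classical ICC(1,1) at two repeats.
Positive values mean the within-subject error is smaller than the
between-subject error, i.e. the metric carries an individual fingerprint.
Values are categorized on the conventional agreement scale: low
(0 < ICC ≤ 0.2), fair (0.2 < ICC ≤ 0.4), moderate (0.4 < ICC ≤ 0.6),
substantial (0.6 < ICC ≤ 0.8) and almost perfect (0.8 < ICC ≤ 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import StateMetrics, TransitionModel

__all__ = ["ICCResult", "icc", "icc_report", "categorize_icc"]


@dataclass
class ICCResult:
    icc: float
    mse_within: float
    mse_between: float
    n_subjects: int
    metric_name: str
    category: str
    n_dropped: int = 0


def categorize_icc(value: float) -> str:
    """Agreement category of an ICC value (non-positive values: 'negative')."""
    if not np.isfinite(value):
        return "undefined"
    if value <= 0:
        return "negative"
    if value <= 0.2:
        return "low"
    if value <= 0.4:
        return "fair"
    if value <= 0.6:
        return "moderate"
    if value <= 0.8:
        return "substantial"
    return "almost perfect"


def icc(session1, session2, metric_name: str = "") -> ICCResult:
    """Intra-class correlation between two paired per-subject value vectors.

    Subjects with a missing (NaN) value in either session are dropped
    pairwise; at least 3 complete pairs are required. A metric with zero
    variance in both decompositions is flagged as undefined (NaN).
    """
    x1 = np.asarray(session1, dtype=float)
    x2 = np.asarray(session2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("sessions must be 1-D vectors of equal length")
    keep = np.isfinite(x1) & np.isfinite(x2)
    n_dropped = int((~keep).sum())
    x1, x2 = x1[keep], x2[keep]
    s = x1.size
    if s < 3:
        raise ValueError(f"need at least 3 complete pairs, got {s}")
    means = (x1 + x2) / 2.0
    grand = means.mean()
    mse_b = 2.0 * np.sum((means - grand) ** 2) / (s - 1)
    mse_w = np.sum((x1 - means) ** 2 + (x2 - means) ** 2) / s
    denom = mse_b + mse_w
    if denom == 0:
        value = np.nan
    else:
        value = (mse_b - mse_w) / denom
    return ICCResult(
        icc=float(value),
        mse_within=float(mse_w),
        mse_between=float(mse_b),
        n_subjects=s,
        metric_name=metric_name,
        category=categorize_icc(value),
        n_dropped=n_dropped,
    )


def _check_paired(ids1, ids2) -> None:
    if len(ids1) != len(ids2):
        raise ValueError(
            f"unmatched sessions: {len(ids1)} vs {len(ids2)} subjects"
        )
    mismatched = [f"{a!r}!={b!r}" for a, b in zip(ids1, ids2) if a != b]
    if mismatched:
        raise ValueError("unmatched subject pairing: " + ", ".join(mismatched))


def icc_report(
    metrics_lr: list[StateMetrics],
    models_lr: list[TransitionModel],
    metrics_rl: list[StateMetrics],
    models_rl: list[TransitionModel],
) -> pd.DataFrame:
    """ICC table across two sessions for occupancy, dwell time and W entries.

    Scans must be subject-paired in order (scan_ids are checked when both
    sides carry them). Returns one row per state for occupancy and dwell
    time and one per (α, β) entry of the transition matrix, with columns
    metric, state, icc, mse_within, mse_between, n_used, category.
    """
    _check_paired([m.scan_id for m in metrics_lr],
                  [m.scan_id for m in metrics_rl])
    _check_paired([m.scan_id for m in models_lr],
                  [m.scan_id for m in models_rl])
    k = metrics_lr[0].k
    rows = []

    def add(metric, state, v1, v2):
        try:
            res = icc(v1, v2, metric_name=metric)
        except ValueError:
            return
        rows.append({
            "metric": metric, "state": state, "icc": res.icc,
            "mse_within": res.mse_within, "mse_between": res.mse_between,
            "n_used": res.n_subjects, "category": res.category,
        })

    occ_lr = np.array([m.occupancy for m in metrics_lr])
    occ_rl = np.array([m.occupancy for m in metrics_rl])
    dt_lr = np.array([m.dwell_time for m in metrics_lr])
    dt_rl = np.array([m.dwell_time for m in metrics_rl])
    for a in range(k):
        add("occupancy", f"{a + 1}", occ_lr[:, a], occ_rl[:, a])
    for a in range(k):
        add("dwell_time", f"{a + 1}", dt_lr[:, a], dt_rl[:, a])
    w_lr = np.stack([m.conditional for m in models_lr])
    w_rl = np.stack([m.conditional for m in models_rl])
    for a in range(k):
        for b in range(k):
            add("transition", f"{a + 1}->{b + 1}",
                w_lr[:, a, b], w_rl[:, a, b])
    return pd.DataFrame(rows)
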