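"""Occupancy, dwell times and Markov transition statistics of state sequences.

All quantities are estimated separately per scan, assuming stationarity of
the state trajectory within each scan:

- fractional occupancy Π_α = (# samples in state α) / T
- dwell time DT_α = mean length of the maximal runs of α, in seconds
- joint transition probability Π_αβ = (# consecutive α→β pairs) / (T − 1)
- conditional transition matrix W_αβ = Π_αβ / Π'_α

By default Π'_α is the occupancy over the first T − 1 samples, which makes W
exactly row-stochastic (Σ_β Π_αβ = Π'_α holds as an identity). Setting
``eq4_literal=True`` divides instead by the occupancy over all T samples,
leaving rows summing to 1 ± O(1/T); the discrepancy is at most one sample's
worth of probability. States never occupied (in the relevant window) get
missing (NaN) dwell times and W rows, not zeros, so group averages are not
biased by absent states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import StateSequence

__all__ = [
    "StateMetrics",
    "TransitionModel",
    "fractional_occupancy",
    "dwell_times",
    "state_metrics",
    "transition_model",
    "group_transition_matrix",
    "export_transition_graph",
    "write_graphml",
    "write_dot",
]


@dataclass
class StateMetrics:
    """Per-scan occupancy and dwell-time summary."""

    occupancy: np.ndarray          # (k,) fractions, sums to 1
    dwell_time: np.ndarray         # (k,) seconds; NaN where the state is absent
    n_runs: np.ndarray             # (k,) run counts p_alpha
    run_lengths: list[np.ndarray]  # per-state run lengths in TR counts
    scan_id: str
    tr: float

    @property
    def k(self) -> int:
        return self.occupancy.shape[0]


@dataclass
class TransitionModel:
    """Per-scan joint (Π_αβ) and conditional (W_αβ) transition matrices."""

    joint: np.ndarray        # (k, k), sums to 1 over all entries
    conditional: np.ndarray  # (k, k); rows of absent states are NaN
    n_pairs: int             # T - 1
    scan_id: str

    @property
    def k(self) -> int:
        return self.joint.shape[0]


def _labels(seq) -> tuple[np.ndarray, int, str, float | None]:
    if isinstance(seq, StateSequence):
        return seq.labels, seq.k, seq.scan_id, seq.tr
    labels = np.asarray(seq, dtype=int)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("need a non-empty 1-D label sequence")
    if labels.min() < 1:
        raise ValueError("labels are 1-based")
    return labels, int(labels.max()), "", None


def fractional_occupancy(seq, k: int | None = None) -> np.ndarray:
    """Fraction of samples spent in each state: Π_α = count(α) / T."""
    labels, k_seq, _, _ = _labels(seq)
    k = k_seq if k is None else k
    return np.bincount(labels - 1, minlength=k) / labels.size


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs as (state, length) pairs, in temporal order."""
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [labels.size - 1]))
    return labels[starts], ends - starts + 1


def dwell_times(
    seq,
    tr: float | None = None,
    k: int | None = None,
    include_boundary_runs: bool = True,
) -> StateMetrics:
    """Mean visit duration per state, via maximal-run decomposition.

    ``include_boundary_runs=False`` drops the first and last run of the scan
    (their durations are truncated by the recording window); a state whose
    only runs touch a boundary then gets a missing dwell time.
    """
    labels, k_seq, scan_id, seq_tr = _labels(seq)
    k = k_seq if k is None else k
    if tr is None:
        tr = seq_tr
    if tr is None or tr <= 0:
        raise ValueError("a positive tr (seconds) is required")
    states, lengths = _runs(labels)
    if not include_boundary_runs:
        keep = np.ones(states.size, dtype=bool)
        keep[0] = keep[-1] = False
        states, lengths = states[keep], lengths[keep]
    run_lengths = [lengths[states == a + 1] for a in range(k)]
    dt = np.array([r.mean() * tr if r.size else np.nan for r in run_lengths])
    n_runs = np.array([r.size for r in run_lengths])
    return StateMetrics(
        occupancy=fractional_occupancy(labels, k),
        dwell_time=dt,
        n_runs=n_runs,
        run_lengths=run_lengths,
        scan_id=scan_id,
        tr=float(tr),
    )


def state_metrics(seq, tr: float | None = None, k: int | None = None,
                  include_boundary_runs: bool = True) -> StateMetrics:
    """Alias for :func:`dwell_times` (occupancy + dwell summary per scan)."""
    return dwell_times(seq, tr=tr, k=k,
                       include_boundary_runs=include_boundary_runs)


def transition_model(seq, k: int | None = None,
                     eq4_literal: bool = False) -> TransitionModel:
    """Joint and conditional state-transition matrices of one scan."""
    labels, k_seq, scan_id, _ = _labels(seq)
    k = k_seq if k is None else k
    if labels.size < 2:
        raise ValueError("transition estimation needs at least 2 samples")
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1.0)
    n_pairs = labels.size - 1
    joint = counts / n_pairs
    if eq4_literal:
        marginal = fractional_occupancy(labels, k)
    else:
        marginal = np.bincount(labels[:-1] - 1, minlength=k) / n_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        conditional = joint / marginal[:, None]
    conditional[marginal == 0] = np.nan
    return TransitionModel(joint, conditional, n_pairs, scan_id)


def group_transition_matrix(models) -> np.ndarray:
    """Element-wise mean of W across scans, skipping missing (NaN) rows."""
    models = list(models)
    if not models:
        raise ValueError("need at least one transition model")
    k = models[0].k
    if any(m.k != k for m in models):
        raise ValueError("all transition models must share the same k")
    stack = np.stack([m.conditional for m in models])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def export_transition_graph(w: np.ndarray, threshold: float = 0.0,
                            occupancy: np.ndarray | None = None):
    """Directed weighted graph with an edge α→β for every W_αβ > threshold.

    Self-loops are kept. Nodes are 1-based state indices and carry an
    ``occupancy`` attribute when provided.
    """
    import networkx as nx

    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("transition matrix must be square")
    k = w.shape[0]
    g = nx.DiGraph()
    for a in range(k):
        attrs = {"state": a + 1}
        if occupancy is not None:
            attrs["occupancy"] = float(occupancy[a])
        g.add_node(a + 1, **attrs)
    for a in range(k):
        for b in range(k):
            if np.isfinite(w[a, b]) and w[a, b] > threshold:
                g.add_edge(a + 1, b + 1, weight=float(w[a, b]))
    return g


def write_graphml(graph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph, path)


def write_dot(graph, path) -> None:
    """Minimal Graphviz DOT serialization of the transition graph."""
    lines = ["digraph transitions {"]
    for node, attrs in graph.nodes(data=True):
        label = f"S{node}"
        if "occupancy" in attrs:
            label += f"\\n{attrs['occupancy']:.3f}"
        lines.append(f'  {node} [label="{label}"];')
    for a, b, attrs in graph.edges(data=True):
        lines.append(f'  {a} -> {b} [weight={attrs["weight"]:.17g}, '
                     f'label="{attrs["weight"]:.2f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
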