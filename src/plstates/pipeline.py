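"""End-to-end orchestration: signals → eigenvectors → states → metrics.

``analyze_scans`` is the in-memory pipeline; ``run_pipeline`` wraps it with
file I/O, a validated :class:`RunConfig`, stage logging and a JSON manifest
(config, package versions and SHA-256 checksums of every written file), so a
run is fully reproducible from its output directory. Clustering is fitted on
the pooled discovery session only; validation scans are projected onto the
fitted centroids without refitting.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as plio
from .clustering import assign_to_centroids, fit_kmeans, silhouette_score
from .dynamics import (export_transition_graph, group_transition_matrix,
                       state_metrics, transition_model, write_dot,
                       write_graphml)
from .leida import eigenvector_series
from .overlap import ReferenceNetworks, centroid_network_overlap
from .preprocess import bandpass_filter
from .reliability import icc_report

__all__ = ["RunConfig", "PipelineResult", "analyze_scans", "run_pipeline"]

log = logging.getLogger("plstates")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    discovery: list[str]
    out_dir: str
    validation: list[str] = field(default_factory=list)
    f_low: float | None = None
    f_high: float | None = None
    filter_order: int = 2
    k: int = 5
    n_replicates: int = 100
    seed: int = 0
    eq4_literal: bool = False
    include_boundary_runs: bool = True
    silhouette_subsample: int = 20000
    reference: str | None = None  # TSV (M x N) with sidecar names/labels

    def __post_init__(self) -> None:
        if not self.discovery:
            raise ValueError("at least one discovery scan is required")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if (self.f_low is None) != (self.f_high is None):
            raise ValueError("specify both filter edges or neither")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**plio.read_json(path))


@dataclass
class PipelineResult:
    """In-memory bundle returned by :func:`analyze_scans`."""

    centroids: object
    discovery_sequences: list
    validation_sequences: list
    discovery_metrics: list
    validation_metrics: list
    discovery_models: list
    validation_models: list
    group_w: np.ndarray
    group_occupancy: np.ndarray
    silhouette: float
    icc_table: pd.DataFrame | None
    overlap: object | None


def analyze_scans(
    discovery,
    validation=(),
    *,
    k: int = 5,
    n_replicates: int = 100,
    seed: int = 0,
    f_low: float | None = None,
    f_high: float | None = None,
    filter_order: int = 2,
    eq4_literal: bool = False,
    include_boundary_runs: bool = True,
    silhouette_subsample: int = 20000,
    reference: ReferenceNetworks | None = None,
) -> PipelineResult:
    """Run the full state analysis on in-memory BOLD scans."""
    discovery = list(discovery)
    validation = list(validation)
    if f_low is not None:
        log.info("filtering %d scans to band %.4g-%.4g Hz",
                 len(discovery) + len(validation), f_low, f_high)
        discovery = [bandpass_filter(ts, f_low, f_high, filter_order)
                     for ts in discovery]
        validation = [bandpass_filter(ts, f_low, f_high, filter_order)
                      for ts in validation]

    disc_eigs = [eigenvector_series(ts) for ts in discovery]
    val_eigs = [eigenvector_series(ts) for ts in validation]
    pooled = sum(e.n_samples for e in disc_eigs)
    log.info("LEiDA: %d discovery scans, %d pooled observations of dim %d",
             len(disc_eigs), pooled, disc_eigs[0].n_regions)

    cset, disc_seqs = fit_kmeans(disc_eigs, k, n_replicates=n_replicates,
                                 seed=seed)
    sil = silhouette_score(disc_eigs, disc_seqs,
                           subsample_size=silhouette_subsample, seed=seed)
    log.info("clustering: k=%d, inertia=%.4f, silhouette=%.4f",
             k, cset.fit_inertia, sil)
    val_seqs = (assign_to_centroids(val_eigs, cset) if val_eigs else [])

    def summarize(scans, seqs):
        metrics, models = [], []
        for ts, seq in zip(scans, seqs):
            metrics.append(state_metrics(
                seq, tr=ts.tr, k=k,
                include_boundary_runs=include_boundary_runs))
            models.append(transition_model(seq, k=k,
                                           eq4_literal=eq4_literal))
        return metrics, models

    disc_metrics, disc_models = summarize(discovery, disc_seqs)
    val_metrics, val_models = summarize(validation, val_seqs)

    group_w = group_transition_matrix(disc_models)
    group_occ = np.mean([m.occupancy for m in disc_metrics], axis=0)

    icc_table = None
    if validation:
        icc_table = icc_report(disc_metrics, disc_models,
                               val_metrics, val_models)
    else:
        log.warning("no validation session supplied; ICC table skipped")

    overlap = None
    if reference is not None:
        overlap = centroid_network_overlap(cset, reference)
        log.info("overlap: best matches %s", overlap.best_match)

    return PipelineResult(
        centroids=cset,
        discovery_sequences=disc_seqs,
        validation_sequences=val_seqs,
        discovery_metrics=disc_metrics,
        validation_metrics=val_metrics,
        discovery_models=disc_models,
        validation_models=val_models,
        group_w=group_w,
        group_occupancy=group_occ,
        silhouette=sil,
        icc_table=icc_table,
        overlap=overlap,
    )


def _metrics_frame(metrics) -> pd.DataFrame:
    rows = []
    for m in metrics:
        for a in range(m.k):
            rows.append({
                "scan_id": m.scan_id, "state": a + 1,
                "occupancy": m.occupancy[a],
                "dwell_time_s": m.dwell_time[a],
                "n_runs": m.n_runs[a],
            })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load scans per config, run :func:`analyze_scans`, write the bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    discovery = [plio.read_bold(p) for p in config.discovery]
    validation = [plio.read_bold(p) for p in config.validation]
    reference = None
    if config.reference is not None:
        ref_meta = plio.read_json(Path(config.reference).with_suffix(".json"))
        reference = ReferenceNetworks(
            plio.read_matrix(config.reference),
            ref_meta["network_names"], ref_meta["region_labels"],
        )

    result = analyze_scans(
        discovery, validation,
        k=config.k, n_replicates=config.n_replicates, seed=config.seed,
        f_low=config.f_low, f_high=config.f_high,
        filter_order=config.filter_order,
        eq4_literal=config.eq4_literal,
        include_boundary_runs=config.include_boundary_runs,
        silhouette_subsample=config.silhouette_subsample,
        reference=reference,
    )

    written: list[Path] = []

    def emit(path: Path):
        written.append(path)
        return path

    plio.write_matrix(result.centroids.centroids, emit(out / "centroids.tsv"))
    for tag, seqs in (("discovery", result.discovery_sequences),
                      ("validation", result.validation_sequences)):
        for seq in seqs:
            plio.write_labels(
                seq, emit(out / f"labels_{seq.scan_id}_{tag}.tsv"))
    _metrics_frame(result.discovery_metrics).to_csv(
        emit(out / "metrics_discovery.tsv"), sep="\t", index=False)
    if result.validation_metrics:
        _metrics_frame(result.validation_metrics).to_csv(
            emit(out / "metrics_validation.tsv"), sep="\t", index=False)
    plio.write_matrix(result.group_w, emit(out / "group_transition.tsv"))
    graph = export_transition_graph(result.group_w,
                                    occupancy=result.group_occupancy)
    write_graphml(graph, emit(out / "group_transition.graphml"))
    write_dot(graph, emit(out / "group_transition.dot"))
    if result.icc_table is not None:
        result.icc_table.to_csv(emit(out / "icc.tsv"), sep="\t", index=False)
    if result.overlap is not None:
        plio.write_matrix(result.overlap.r_matrix, emit(out / "overlap_r.tsv"))
        plio.write_matrix(result.overlap.p_matrix, emit(out / "overlap_p.tsv"))
        plio.write_json(
            {"best_match": result.overlap.best_match,
             "alpha_corrected": result.overlap.alpha_corrected},
            emit(out / "overlap_best.json"))

    import networkx
    import scipy
    import sklearn

    from . import __version__

    manifest = {
        "config": asdict(config),
        "versions": {
            "plstates": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
        "counts": {
            "discovery_scans": len(discovery),
            "validation_scans": len(validation),
            "pooled_observations": int(
                sum(len(s) for s in result.discovery_sequences)),
            "retained_trs_per_scan": [
                len(s) for s in result.discovery_sequences],
        },
        "silhouette": result.silhouette,
        "checksums": {p.name: _sha256(p) for p in written},
    }
    plio.write_json(manifest, out / "manifest.json")
    return result
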