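"""Readers and writers for the plain-text interchange formats.

Signals and eigenvector series travel as tab-separated matrices with a JSON
sidecar (same stem, ``.json`` suffix) holding tr, labels and identifiers.
State label sequences are one integer per line; tables are TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .clustering import StateSequence
from .leida import LeadingEigSeries
from .preprocess import BOLDTimeSeries

__all__ = [
    "read_bold", "write_bold",
    "read_eigs", "write_eigs",
    "read_labels", "write_labels",
    "read_matrix", "write_matrix",
    "read_json", "write_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_matrix(arr, path) -> None:
    np.savetxt(path, np.asarray(arr, dtype=float), delimiter="\t",
               fmt="%.17g")


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_bold(ts: BOLDTimeSeries, path) -> None:
    """Write a regions × samples TSV plus its JSON sidecar."""
    path = Path(path)
    write_matrix(ts.data, path)
    write_json(
        {
            "tr": ts.tr,
            "region_labels": ts.region_labels,
            "scan_id": ts.scan_id,
            "session_tag": ts.session_tag,
            "meta": ts.meta,
        },
        _sidecar(path),
    )


def read_bold(path, sidecar=None) -> BOLDTimeSeries:
    path = Path(path)
    meta = read_json(_sidecar(path) if sidecar is None else sidecar)
    return BOLDTimeSeries(
        read_matrix(path),
        tr=float(meta["tr"]),
        region_labels=meta["region_labels"],
        scan_id=meta.get("scan_id", path.stem),
        session_tag=meta.get("session_tag", ""),
        meta=meta.get("meta", {}),
    )


def write_eigs(eigs: LeadingEigSeries, path) -> None:
    """Write a samples × regions TSV of V1(t) plus a JSON sidecar."""
    path = Path(path)
    write_matrix(eigs.vectors, path)
    write_json(
        {
            "tr": eigs.tr,
            "scan_id": eigs.scan_id,
            "region_labels": eigs.region_labels,
            "eigenvalues": eigs.eigenvalues.tolist(),
            "trim": "first and last samples of the scan removed",
        },
        _sidecar(path),
    )


def read_eigs(path, sidecar=None) -> LeadingEigSeries:
    path = Path(path)
    meta = read_json(_sidecar(path) if sidecar is None else sidecar)
    vectors = read_matrix(path)
    return LeadingEigSeries(
        vectors,
        np.asarray(meta["eigenvalues"], dtype=float),
        tr=float(meta["tr"]),
        scan_id=meta.get("scan_id", path.stem),
        region_labels=meta.get("region_labels"),
    )


def write_labels(seq: StateSequence, path) -> None:
    np.savetxt(path, seq.labels, fmt="%d")
    write_json({"scan_id": seq.scan_id, "k": seq.k, "tr": seq.tr},
               _sidecar(Path(path)))


def read_labels(path, k: int | None = None) -> StateSequence:
    path = Path(path)
    labels = np.loadtxt(path, dtype=int)
    side = _sidecar(path)
    meta = read_json(side) if side.exists() else {}
    return StateSequence(
        np.atleast_1d(labels),
        scan_id=meta.get("scan_id", path.stem),
        k=int(meta.get("k", k if k is not None else labels.max())),
        tr=meta.get("tr"),
    )
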