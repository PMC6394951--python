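"""Plain-text readers and writers for every pipeline artifact.

All numeric formats are diffable text: TSV matrices written with 17 significant
digits (exact float64 round-trip), JSON sidecar
manifests, and BrainNet-Viewer-dialect ``.node``/``.edge`` files for the
significant networks.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnMatrix
from .epochs import EpochSet
from .netstats import Edge, NetworkResult, node_degrees

__all__ = [
    "FLOAT_FMT",
    "roi_table",
    "write_epochset",
    "read_epochset",
    "write_connmatrix",
    "read_connmatrix",
    "write_network_result",
    "read_network_result",
    "write_network_files",
    "read_network_files",
]

FLOAT_FMT = "%.17g"


def roi_table(n_rois: int | None = None) -> pd.DataFrame:
    """Bundled cortical parcel labels with hemisphere and lobe.

    The full table holds 2 x 22 regions (frontal, cingular, temporal,
    parietal); ``n_rois`` truncates it for smaller simulations.
    """
    with resources.files("plinet.data").joinpath("roi_labels.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if n_rois is not None:
        if n_rois > len(df):
            raise ValueError(f"table has only {len(df)} ROIs")
        df = df.iloc[:n_rois].reset_index(drop=True)
    return df


# -- epochs ----------------------------------------------------------------

def write_epochset(epochs: EpochSet, path) -> None:
    """One flat numeric TSV (epochs*channels rows) plus a JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = epochs.data.reshape(-1, epochs.n_samples)
    np.savetxt(path, flat, fmt=FLOAT_FMT, delimiter="\t")
    manifest = {
        "shape": list(epochs.data.shape),
        "fs": epochs.fs,
        "labels": list(epochs.labels),
        "subject": epochs.subject,
        "condition": epochs.condition,
        "meta": _jsonable(epochs.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))


def read_epochset(path) -> EpochSet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    shape = tuple(manifest["shape"])
    flat = np.loadtxt(path, delimiter="\t", ndmin=2)
    return EpochSet(data=flat.reshape(shape), fs=manifest["fs"],
                    labels=manifest["labels"], subject=manifest["subject"],
                    condition=manifest["condition"],
                    meta=manifest.get("meta", {}))


# -- connectivity matrices -------------------------------------------------

def write_connmatrix(matrix: ConnMatrix, path) -> None:
    """Square TSV with an ROI-label header row plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.labels) + "\n")
        for row in matrix.values:
            fh.write("\t".join(FLOAT_FMT % x for x in row) + "\n")
    sidecar = {"band": matrix.band, "subject": matrix.subject,
               "condition": matrix.condition, "n_epochs": matrix.n_epochs}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def read_connmatrix(path) -> ConnMatrix:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ConnMatrix(values=values, labels=labels, **sidecar)


# -- network results -------------------------------------------------------

def write_network_result(result: NetworkResult, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "threshold": result.threshold,
        "p_fwe": result.p_fwe,
        "p_at_threshold": result.p_at_threshold,
        "alpha": result.alpha,
        "labels": list(result.labels),
        "edges": [[e.i, e.j, e.f, e.mean_diff] for e in result.edges],
        "thresholds": [float(t) for t in result.thresholds],
        "p_per_threshold": [float(p) for p in result.p_per_threshold],
        "observed_sizes": [int(s) for s in result.observed_sizes],
        "meta": _jsonable(result.meta),
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_network_result(path) -> NetworkResult:
    doc = json.loads(Path(path).read_text())
    return NetworkResult(
        threshold=doc["threshold"],
        edges=[Edge(int(i), int(j), float(f), float(d))
               for i, j, f, d in doc["edges"]],
        p_fwe=doc["p_fwe"],
        labels=doc["labels"],
        alpha=doc["alpha"],
        thresholds=np.array(doc["thresholds"]),
        p_per_threshold=np.array(doc["p_per_threshold"]),
        observed_sizes=np.array(doc["observed_sizes"]),
        p_at_threshold=doc["p_at_threshold"],
        meta=doc.get("meta", {}),
    )


# -- BrainNet-dialect node/edge files -------------------------------------

def write_network_files(result: NetworkResult, roi_table: pd.DataFrame,
                        stem) -> tuple[Path, Path]:
    """Write ``<stem>.node`` and ``<stem>.edge`` text files.

    ``roi_table`` must carry one row per ROI in ``result.labels`` order;
    columns ``x``, ``y``, ``z`` are used if present, otherwise zero
    placeholders.  The ``.node`` file holds ``x y z color size label``
    with node degree as size; ``.edge`` is the square symmetric weight
    (F value) matrix of the network.
    """
    if len(roi_table) != len(result.labels):
        raise ValueError(
            f"ROI table has {len(roi_table)} rows for {len(result.labels)} labels")
    if "label" in roi_table.columns:
        mism = [a for a, b in zip(roi_table["label"], result.labels) if a != b]
        if mism:
            raise ValueError(f"ROI table labels disagree with result: {mism[:5]}")
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    n = len(result.labels)
    deg = node_degrees(result.edges, n_rois=n)
    coords = np.zeros((n, 3))
    for k, c in enumerate("xyz"):
        if c in roi_table.columns:
            coords[:, k] = roi_table[c].to_numpy(dtype=float)
    node_path = stem.with_suffix(".node")
    with open(node_path, "w") as fh:
        for r in range(n):
            fh.write(f"{coords[r, 0]:.3f}\t{coords[r, 1]:.3f}\t"
                     f"{coords[r, 2]:.3f}\t1\t{deg[r]}\t{result.labels[r]}\n")
    adj = np.zeros((n, n))
    for e in result.edges:
        adj[e.i, e.j] = adj[e.j, e.i] = e.f
    edge_path = stem.with_suffix(".edge")
    np.savetxt(edge_path, adj, fmt=FLOAT_FMT, delimiter="\t")
    return node_path, edge_path


def read_network_files(stem) -> tuple[pd.DataFrame, np.ndarray]:
    """Round-trip reader for the ``.node``/``.edge`` pair."""
    stem = Path(stem)
    nodes = pd.read_csv(stem.with_suffix(".node"), sep="\t", header=None,
                        names=["x", "y", "z", "color", "size", "label"])
    adj = np.loadtxt(stem.with_suffix(".edge"), delimiter="\t", ndmin=2)
    return nodes, adj


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
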