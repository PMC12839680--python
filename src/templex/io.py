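"""Delimited-text I/O for time series, adjacency matrices, and manifests.

Per-subject matrices are TSV/CSV with a leading ROI-label column and one
column per timepoint; adjacency matrices carry node labels as both header
row and first column.  Orientation of time-series files is taken as
ROI x timepoint (rows = ROIs); files are rejected rather than silently
transposed when the label column is not present.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .multiplex import MultiplexNetwork

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_adjacency",
    "write_adjacency",
    "read_manifest",
    "write_multiplex",
    "read_multiplex",
    "export_graphml",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a ROI x timepoint matrix; returns (matrix, roi_labels).

    The first column holds ROI labels; all remaining cells must be numeric.
    Duplicate labels and non-numeric cells are reported with coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0)
    labels = [str(x) for x in df.index]
    if len(set(labels)) != len(labels):
        dup = next(x for x in labels if labels.count(x) > 1)
        raise ValueError(f"{path}: duplicate ROI label {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna() & df[col].notna())
        if bad.size or converted.isna().any():
            row = int(bad[0]) if bad.size else int(np.flatnonzero(converted.isna())[0])
            raise ValueError(
                f"{path}: non-numeric cell at ROI {labels[row]!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return values, labels


def write_timeseries(
    path: str | Path, matrix: np.ndarray, roi_labels: list[str]
) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.asarray(matrix),
        index=pd.Index(roi_labels, name="roi"),
        columns=[f"t{j}" for j in range(np.asarray(matrix).shape[1])],
    )
    df.to_csv(path, sep=_sep_for(path))


def read_adjacency(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column labels disagree")
    return df.to_numpy(dtype=float), [str(x) for x in df.index]


def write_adjacency(
    path: str | Path, matrix: np.ndarray, node_labels: list[str]
) -> None:
    path = Path(path)
    pd.DataFrame(
        np.asarray(matrix), index=pd.Index(node_labels, name="node"),
        columns=node_labels,
    ).to_csv(path, sep=_sep_for(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a subject manifest CSV with subject_id, group, path columns."""
    df = pd.read_csv(path)
    missing = {"subject_id", "group", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_multiplex(
    net: MultiplexNetwork, out_dir: str | Path, prefix: str = "",
    metadata: dict | None = None,
) -> None:
    """Write one labeled TSV adjacency per layer plus a JSON metadata record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, w in zip(net.layer_names, net.layers):
        write_adjacency(out / f"{prefix}{name}.tsv", w, net.node_labels)
    if metadata is not None:
        (out / f"{prefix}metadata.json").write_text(json.dumps(metadata, indent=2))


def read_multiplex(
    in_dir: str | Path, layer_names: list[str], prefix: str = ""
) -> MultiplexNetwork:
    in_dir = Path(in_dir)
    layers, labels = [], None
    for name in layer_names:
        w, lab = read_adjacency(in_dir / f"{prefix}{name}.tsv")
        if labels is None:
            labels = lab
        elif lab != labels:
            raise ValueError(f"layer {name!r} has mismatched node labels")
        layers.append(w)
    return MultiplexNetwork(layers=layers, layer_names=list(layer_names),
                            node_labels=labels or [])


def export_graphml(net: MultiplexNetwork, out_dir: str | Path, prefix: str = "") -> None:
    """One GraphML file per layer, for external network viewers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, w in zip(net.layer_names, net.layers):
        g = nx.from_numpy_array(w, create_using=nx.DiGraph)
        nx.relabel_nodes(g, dict(enumerate(net.node_labels)), copy=False)
        nx.write_graphml(g, out / f"{prefix}{name}.graphml")
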