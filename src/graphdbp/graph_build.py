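"""Protein-graph construction from contact maps and node features.

A protein of length M becomes an undirected graph on M residue nodes:
edges are residue pairs whose contact probability clears the 0.5
threshold, node attributes are the 54 features from :mod:`features`.
Isolated residues are kept — the self-loop added inside the convolution
keeps their features propagating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .io_formats import ContactMap, ProteinRecord, read_label_manifest, write_label_manifest

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary symmetric adjacency with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"adjacency must be square, got {v.shape}")
        if not np.array_equal(v, v.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.trace(v) != 0:
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ProteinGraph:
    """Node features (M×54) + adjacency (M×M) + optional label, for one protein."""

    id: str
    features: np.ndarray
    adjacency: AdjacencyMatrix
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.adjacency.n_nodes:
            raise ValueError(
                f"graph {self.id!r}: {self.features.shape[0]} feature rows vs "
                f"{self.adjacency.n_nodes}-node adjacency"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"graph {self.id!r}: label must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.n_nodes


def binarize_contact_map(cmap: ContactMap, threshold: float = DEFAULT_THRESHOLD) -> AdjacencyMatrix:
    """Threshold contact probabilities into a binary adjacency.

    Probability >= threshold becomes an edge; everything else 0.  The
    diagonal is forced to 0 afterwards (self-loops are added analytically
    in the convolution's normalization).
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    a = (cmap.values >= threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return AdjacencyMatrix(values=a)


def assemble_graph(record: ProteinRecord, features: np.ndarray,
                   adjacency: AdjacencyMatrix,
                   label: Optional[int] = None) -> ProteinGraph:
    """Bundle features + adjacency + label into an immutable graph."""
    if features.shape[0] != len(record):
        raise ValueError(
            f"{record.id!r}: {features.shape[0]} feature rows vs sequence length {len(record)}"
        )
    if label is None:
        label = record.label
    return ProteinGraph(id=record.id, features=features, adjacency=adjacency, label=label)


def graph_stats(graph: ProteinGraph) -> Dict[str, float]:
    """Node/edge counts, density and isolated-node count, for QC logging."""
    a = graph.adjacency.values
    m = graph.n_nodes
    edges = int(a.sum()) // 2
    pairs = m * (m - 1) // 2
    degrees = a.sum(axis=1)
    return {
        "n_nodes": m,
        "n_edges": edges,
        "density": edges / pairs if pairs else 0.0,
        "n_isolated": int((degrees == 0).sum()),
    }


def save_graph_dir(path, graphs: List[ProteinGraph]) -> None:
    """Serialize graphs to ``<id>.features.txt`` / ``<id>.adj.txt`` + labels.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    labels: Dict[str, int] = {}
    for g in graphs:
        np.savetxt(path / f"{g.id}.features.txt", g.features, fmt="%.17g")
        np.savetxt(path / f"{g.id}.adj.txt", g.adjacency.values, fmt="%d")
        if g.label is not None:
            labels[g.id] = g.label
    if labels:
        write_label_manifest(path / "labels.tsv", labels)


def load_graph_dir(path) -> List[ProteinGraph]:
    """Inverse of :func:`save_graph_dir`; graphs sorted by id."""
    path = Path(path)
    labels: Dict[str, int] = {}
    manifest = path / "labels.tsv"
    if manifest.exists():
        labels = read_label_manifest(manifest)
    graphs = []
    for feat_file in sorted(path.glob("*.features.txt")):
        gid = feat_file.name[: -len(".features.txt")]
        features = np.loadtxt(feat_file, ndmin=2)
        adj = np.loadtxt(path / f"{gid}.adj.txt", dtype=np.int8, ndmin=2)
        graphs.append(
            ProteinGraph(
                id=gid,
                features=features,
                adjacency=AdjacencyMatrix(values=adj),
                label=labels.get(gid),
            )
        )
    return graphs
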