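"""Mutual k-nearest-neighbor graphs over spots and pseudo-spots.

Three graph families feed the model: a spatial graph over SRT spots (Euclidean
distance between coordinates), an expression graph over SRT spots (cosine
distance between preprocessed profiles), and many small expression graphs over
disjoint chunks of pseudo-spots.  An edge exists only when each endpoint is
among the other's k nearest neighbors, so adjacency is symmetric by
construction and isolated nodes are possible (the model adds self-loops, so
features still propagate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .data import SpotCoordinates


@dataclass
class SpotGraph:
    """Node features + symmetric binary adjacency + domain flag for one graph."""

    X: np.ndarray                    # (n, g) preprocessed node features
    A: np.ndarray                    # (n, n) symmetric binary, zero diagonal
    domain: int                      # 1 = SRT spots, 0 = pseudo-spots
    node_ids: List[str]
    y: Optional[np.ndarray] = None   # (n, CT) true proportions when known

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape must match node count")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.domain not in (0, 1):
            raise ValueError("domain flag must be 0 or 1")
        if self.y is not None and not np.allclose(self.y.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("y rows must lie on the simplex")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _distance_matrix(points: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(points, points)
    if metric == "cosine":
        norms = np.linalg.norm(points, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        unit = points / safe[:, None]
        sim = unit @ unit.T
        sim[norms == 0, :] = 0.0  # zero vectors: similarity 0 with everything
        sim[:, norms == 0] = 0.0
        return 1.0 - sim
    raise ValueError(f"unknown metric: {metric!r}")


def mutual_knn(points: np.ndarray, k: int, metric: str = "euclidean") -> np.ndarray:
    """Symmetric mutual-kNN adjacency; distance ties broken by ascending node index."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = _distance_matrix(points, metric)
    np.fill_diagonal(d, np.inf)
    kk = min(k, n - 1)
    idx = np.arange(n)
    nn = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.lexsort((idx, d[i]))  # distance first, index breaks ties
        nn[i, order[:kk]] = True
    A = (nn & nn.T).astype(float)
    return A


def build_srt_graphs(
    X: np.ndarray,
    coords: SpotCoordinates,
    node_ids: List[str],
    k: int = 6,
) -> tuple:
    """The two SRT graphs (spatial, expression) over the identical node set."""
    if list(coords.unit_ids) != list(node_ids):
        raise ValueError("coordinate ids do not match feature row ids")
    if X.shape[0] != len(node_ids):
        raise ValueError("feature rows do not match node ids")
    spatial = SpotGraph(X=X, A=mutual_knn(coords.xy, k, "euclidean"),
                        domain=1, node_ids=list(node_ids))
    expression = SpotGraph(X=X, A=mutual_knn(X, k, "cosine"),
                           domain=1, node_ids=list(node_ids))
    return spatial, expression


def save_graph(graph: SpotGraph, prefix: Union[str, Path]) -> None:
    """Cache a graph as edge-list TSV + node-feature MTX + JSON metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ii, jj = np.nonzero(np.triu(graph.A))
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("source\ttarget\n")
        for i, j in zip(ii, jj):
            fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\n")
    scipy.io.mmwrite(f"{prefix}.features.mtx", sp.coo_matrix(graph.X))
    meta = {"node_ids": graph.node_ids, "domain": graph.domain,
            "y": None if graph.y is None else np.asarray(graph.y).tolist()}
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta))


def load_graph(prefix: Union[str, Path]) -> SpotGraph:
    """Load a graph cached by :func:`save_graph`."""
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    node_ids = [str(u) for u in meta["node_ids"]]
    index = {u: i for i, u in enumerate(node_ids)}
    X = np.asarray(sp.coo_matrix(scipy.io.mmread(f"{prefix}.features.mtx")).todense())
    A = np.zeros((len(node_ids), len(node_ids)))
    with open(f"{prefix}.edges.tsv") as fh:
        next(fh)  # header
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            A[index[a], index[b]] = A[index[b], index[a]] = 1.0
    y = None if meta["y"] is None else np.asarray(meta["y"], dtype=float)
    return SpotGraph(X=X, A=A, domain=int(meta["domain"]), node_ids=node_ids, y=y)


def batch_pseudo_graphs(
    X: np.ndarray,
    y: np.ndarray,
    node_ids: List[str],
    graph_size: int = 200,
    n_graphs: int = 250,
    k: int = 6,
    seed: int = 0,
) -> List[SpotGraph]:
    """Partition pseudo-spots (seeded shuffle) into disjoint internal kNN graphs."""
    n = X.shape[0]
    if graph_size * n_graphs > n:
        raise ValueError(
            f"need {graph_size * n_graphs} pseudo-spots for "
            f"{n_graphs} graphs of {graph_size}, have {n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    graphs = []
    for gi in range(n_graphs):
        members = perm[gi * graph_size:(gi + 1) * graph_size]
        graphs.append(SpotGraph(
            X=X[members],
            A=mutual_knn(X[members], k, "cosine"),
            domain=0,
            node_ids=[node_ids[m] for m in members],
            y=y[members],
        ))
    return graphs
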