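"""Symmetric weighted k-NN patient-similarity graph.

Vertices are participants; two participants are linked when one is among the
other's k nearest neighbors in z-scored biomarker space (union
symmetrization). Edge weights use a Gaussian kernel
``w_ij = exp(-(d_ij / eps)**2)`` with Euclidean distance and a single global
scale ``eps`` (default: the mean k-th-neighbor distance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "GraphConnectivityError",
    "SimilarityGraph",
    "edge_weight",
    "build_knn_graph",
    "connected_components",
    "ensure_connected",
    "save_graph",
    "load_graph",
]


class GraphConnectivityError(RuntimeError):
    """The graph has a connected component with no labeled vertex."""


def edge_weight(dist, epsilon: float):
    """Gaussian similarity ``exp(-(dist/epsilon)**2)``: 1 at distance 0,
    strictly decreasing, always positive. Accepts scalars or arrays."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    d = np.asarray(dist, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    w = np.exp(-((d / epsilon) ** 2))
    return float(w) if np.isscalar(dist) else w


@dataclass
class SimilarityGraph:
    """Symmetric weighted k-NN graph over n participants.

    ``W`` is sparse CSR, symmetric, zero diagonal, off-diagonal stored
    weights in (0, 1].
    """

    W: sp.csr_matrix
    k: int
    epsilon: float
    epsilon_rule: str = "mean_kth_distance"
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.W = sp.csr_matrix(self.W)
        self.degrees = np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def neighborhood(self, i: int) -> np.ndarray:
        """Open neighborhood N_i: vertices with positive weight to i."""
        return self.W.indices[self.W.indptr[i] : self.W.indptr[i + 1]]


def build_knn_graph(
    X: np.ndarray,
    k: int,
    epsilon_rule: str = "mean_kth_distance",
    epsilon: float | None = None,
) -> SimilarityGraph:
    """Build the symmetric Gaussian-weighted k-NN graph.

    Nearest neighbors use exact Euclidean distances; ties at the k-th
    neighbor break toward the lowest vertex index (stable sort), so the edge
    set is deterministic. The edge set is the union of the directed k-NN
    relations; duplicate points (distance 0) get weight 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    if np.any(~np.isfinite(X)):
        raise ValueError("feature matrix contains missing/non-finite values")

    D = squareform(pdist(X, metric="euclidean")) if n > 2 else cdist(X, X)
    np.fill_diagonal(D, np.inf)  # exclude self from neighbor search
    nbr = np.argsort(D, axis=1, kind="stable")[:, :k]
    kth = D[np.arange(n), nbr[:, -1]]

    if epsilon is None:
        if epsilon_rule == "mean_kth_distance":
            epsilon = float(np.mean(kth))
            if epsilon <= 0:
                epsilon = 1.0  # all duplicates: weights are 1 regardless
        else:
            raise ValueError(f"unknown epsilon rule {epsilon_rule!r}")
    else:
        epsilon_rule = "fixed"
        if epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {epsilon}")

    rows = np.repeat(np.arange(n), k)
    cols = nbr.ravel()
    w = edge_weight(D[rows, cols], epsilon)
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # union symmetrization; directed weights agree anyway
    W.setdiag(0)
    W.eliminate_zeros()
    return SimilarityGraph(W, k=k, epsilon=epsilon, epsilon_rule=epsilon_rule)


def connected_components(graph: SimilarityGraph) -> list[np.ndarray]:
    ncomp, labels = _cc(graph.W, directed=False)
    return [np.flatnonzero(labels == c) for c in range(ncomp)]


def ensure_connected(graph: SimilarityGraph, labels, strict: bool = True) -> SimilarityGraph:
    """Validate the labeled-component condition.

    strict=True requires a single connected component; strict=False only
    requires every component to contain at least one labeled vertex (the
    weakest condition under which the Dirichlet problem is well posed).
    Raises :class:`GraphConnectivityError` naming the offending components.
    """
    comps = connected_components(graph)
    if strict and len(comps) > 1:
        raise GraphConnectivityError(
            f"graph has {len(comps)} connected components; strict mode requires 1 "
            f"(component sizes: {[len(c) for c in comps]})"
        )
    labeled = set(int(i) for i in np.asarray(labels.indices if hasattr(labels, "indices") else labels))
    bad = [c for c in comps if not labeled.intersection(map(int, c))]
    if bad:
        desc = "; ".join(f"component of size {len(c)} (e.g. vertex {int(c[0])})" for c in bad)
        raise GraphConnectivityError(f"components without any labeled vertex: {desc}")
    return graph


def save_graph(graph: SimilarityGraph, mtx_path, sidecar_path=None) -> None:
    """Write W in Matrix Market format plus a JSON sidecar (n, k, eps, rule)."""
    mtx_path = Path(mtx_path)
    from scipy.io import mmwrite

    mmwrite(str(mtx_path), sp.coo_matrix(graph.W))
    sidecar = Path(sidecar_path) if sidecar_path else mtx_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "n": graph.n,
                "k": graph.k,
                "epsilon": graph.epsilon,
                "epsilon_rule": graph.epsilon_rule,
            }
        )
    )


def load_graph(mtx_path, sidecar_path=None) -> SimilarityGraph:
    from scipy.io import mmread

    mtx_path = Path(mtx_path)
    if not mtx_path.exists() and mtx_path.with_suffix(".mtx").exists():
        mtx_path = mtx_path.with_suffix(".mtx")
    W = sp.csr_matrix(mmread(str(mtx_path)))
    sidecar = Path(sidecar_path) if sidecar_path else mtx_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return SimilarityGraph(
        W, k=meta["k"], epsilon=meta["epsilon"], epsilon_rule=meta["epsilon_rule"]
    )
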