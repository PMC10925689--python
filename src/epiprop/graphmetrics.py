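"""Weighted graph measures of connectome nodes.

All measures follow the package-wide orientation (``W[j, i]`` = weight of
the edge from ``i`` to ``j``): column sums are outgoing strength, row sums
incoming strength.  Eigenvector centrality defaults to the
outgoing-influence direction — a node is central when the nodes it
projects *to* are central — because the seizure-propagation analysis keys
on the outgoing connectivity of the epileptogenic zone.  Path lengths use
the inverted-weight rule ``l_ji = c_m - c_ji`` (``c_m`` the global maximum
weight), applied to every ordered pair so the graph is complete: the
strongest connection in the network has length zero, absent connections
have the maximal length ``c_m``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .connectome import Connectome

__all__ = [
    "CentralityError",
    "degrees",
    "eigenvector_centrality",
    "shortest_path_lengths",
    "max_outgoing_weight",
    "normalize_measures",
    "node_measures",
]


class CentralityError(RuntimeError):
    """Eigenvector centrality undefined or power iteration failed."""


def _weights(C: Connectome | np.ndarray) -> np.ndarray:
    if isinstance(C, Connectome):
        return C.weights
    return np.asarray(C, dtype=float)


def degrees(C: Connectome | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted out- and in-degree (total outgoing / incoming strength).

    Returns
    -------
    (out_degree, in_degree)
        ``out_degree[i]`` = sum of weights of edges leaving ``i`` (column
        ``i``); ``in_degree[i]`` = sum of weights arriving at ``i`` (row
        ``i``).
    """
    W = _weights(C)
    return W.sum(axis=0), W.sum(axis=1)


def eigenvector_centrality(
    C: Connectome | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    direction: str = "out",
) -> np.ndarray:
    """Per-node eigenvector centrality by power iteration, max-normalized.

    ``direction="out"`` solves x_i ∝ Σ_j w(i→j) x_j (outgoing influence);
    ``direction="in"`` solves x_i ∝ Σ_j w(j→i) x_j.  Iteration runs on
    ``I + M`` so matrices whose leading eigenvalues come in ±λ pairs (pure
    cycles) still converge to the Perron vector.

    Raises
    ------
    CentralityError
        If the leading eigenvalue is ≤ ``tol`` (e.g. a nilpotent /
        strictly triangular matrix) or the iteration does not converge.
    """
    W = _weights(C)
    if direction == "out":
        M = W.T
    elif direction == "in":
        M = W
    else:
        raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")
    n = M.shape[0]
    # acyclic (nilpotent) matrices have leading eigenvalue 0: no cycle of
    # positive weight means every strongly connected component is trivial
    n_comp, comp = csgraph.connected_components(
        csgraph.csgraph_from_dense(M, null_value=0.0), connection="strong"
    )
    if n_comp == n:
        raise CentralityError(
            "centrality undefined: matrix has no positively weighted cycle"
        )
    v = np.ones(n)
    lam = 0.0
    for _ in range(max_iter):
        w = v + M @ v
        top = w.max()
        if top <= 0:
            raise CentralityError("centrality undefined (iteration collapsed to zero)")
        w /= top
        lam = float(v @ (M @ v) / (v @ v))
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    else:
        raise CentralityError(f"power iteration did not converge in {max_iter} iterations")
    if lam <= tol:
        raise CentralityError(
            f"centrality undefined: leading eigenvalue {lam:.3g} ≤ tol "
            "(matrix has no positively weighted cycle)"
        )
    return v / v.max()


def shortest_path_lengths(C: Connectome | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest paths on the inverted-weight complete graph.

    Every ordered pair (i, j), including pairs with zero structural
    weight, is an edge of length ``c_m - c_ji``; pairwise distances are
    computed with Dijkstra's algorithm.  The per-node average
    ``L_i = Σ_j d(i→j) / N`` includes the zero ``j = i`` term.

    Returns
    -------
    (dist, L)
        ``dist[i, j]`` = shortest-path length from ``i`` to ``j``;
        ``L`` = per-node averages.
    """
    W = _weights(C)
    n = W.shape[0]
    c_m = W.max()
    lengths = c_m - W  # lengths[j, i] = length of edge i -> j
    np.fill_diagonal(lengths, 0.0)
    # scipy expects G[i, j] = length of edge i -> j; keep zero-length edges
    G = csgraph.csgraph_from_dense(np.ascontiguousarray(lengths.T), null_value=np.inf)
    dist = csgraph.dijkstra(G, directed=True)
    L = dist.sum(axis=1) / n
    return dist, L


def max_outgoing_weight(C: Connectome | np.ndarray, node: int) -> float:
    """The node's strongest outgoing connection weight (0 if isolated)."""
    W = _weights(C)
    n = W.shape[0]
    if not (-n <= node < n):
        raise IndexError(f"node index {node} out of range for {n} nodes")
    return float(W[:, node].max())


def normalize_measures(raw: dict[str, np.ndarray] | np.ndarray) -> dict[str, np.ndarray] | np.ndarray:
    """Divide each measure by its maximum across nodes (max becomes 1)."""

    def _norm(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        top = v.max()
        if top <= 0:
            raise ValueError("cannot normalize an all-zero measure")
        return v / top

    if isinstance(raw, dict):
        return {k: _norm(v) for k, v in raw.items()}
    return _norm(raw)


def node_measures(C: Connectome, centrality_direction: str = "out") -> pd.DataFrame:
    """All per-node measures plus their max-normalized variants.

    Columns: out_degree, in_degree, eig_centrality, avg_shortest_path,
    max_out_weight and ``*_norm`` counterparts (eigenvector centrality is
    already max-normalized).
    """
    W = C.weights
    out_deg, in_deg = degrees(W)
    try:
        eig = eigenvector_centrality(W, direction=centrality_direction)
    except CentralityError:
        eig = np.full(W.shape[0], np.nan)
    _, L = shortest_path_lengths(W)
    mow = W.max(axis=0)
    df = pd.DataFrame(
        {
            "node": np.arange(W.shape[0]),
            "label": C.labels,
            "out_degree": out_deg,
            "in_degree": in_deg,
            "eig_centrality": eig,
            "avg_shortest_path": L,
            "max_out_weight": mow,
        }
    )
    for col in ["out_degree", "in_degree", "eig_centrality", "avg_shortest_path", "max_out_weight"]:
        top = df[col].max()
        df[col + "_norm"] = df[col] / top if top > 0 else np.nan
    return df
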