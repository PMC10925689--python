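"""Brute-force oracles used to check the graph measures independently."""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_degrees(W: np.ndarray):
    """Loop-based weighted out/in degrees (W[j, i] = weight i -> j)."""
    n = W.shape[0]
    out_deg = np.zeros(n)
    in_deg = np.zeros(n)
    for j in range(n):
        for i in range(n):
            out_deg[i] += W[j, i]
            in_deg[j] += W[j, i]
    return out_deg, in_deg


def brute_max_out(W: np.ndarray, node: int) -> float:
    best = 0.0
    for j in range(W.shape[0]):
        best = max(best, W[j, node])
    return best


def brute_shortest_paths(W: np.ndarray):
    """Exhaustive simple-path enumeration on the inverted-weight complete
    graph (edge i -> j has length c_m - W[j, i]); feasible for n <= 7."""
    n = W.shape[0]
    c_m = W.max()

    def edge_len(a: int, b: int) -> float:
        return c_m - W[b, a]

    dist = np.zeros((n, n))
    nodes = set(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = edge_len(i, j)
            inner = list(nodes - {i, j})
            for k in range(1, len(inner) + 1):
                for mid in permutations(inner, k):
                    path = (i, *mid, j)
                    length = sum(edge_len(a, b) for a, b in zip(path[:-1], path[1:]))
                    best = min(best, length)
            dist[i, j] = best
    L = dist.sum(axis=1) / n
    return dist, L
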