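"""Virtual interventions on the structural connectome.

Two in-silico strategies for confining seizure propagation:

* **edge removal** — a resection-like disconnection of specific
  projections; the listed entries are zeroed and the matrix is
  re-normalized so its global maximum weight is 1 again (the scale on
  which the regime thresholds live);
* **outgoing-weight reduction** — a drug/neuromodulation-like suppression
  of a node's output: all its outgoing weights are scaled by ``1 - p``
  and the whole matrix is rescaled to preserve the total connective
  strength.

Both are pure functions: the input connectome is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .graphmetrics import CentralityError, eigenvector_centrality, max_outgoing_weight

__all__ = [
    "InterventionSpec",
    "remove_edges",
    "reduce_outgoing",
    "apply_intervention",
    "intervention_report",
]


@dataclass
class InterventionSpec:
    """A declarative intervention.

    ``kind="remove_edges"`` uses ``edges`` (ordered ``(source, target)``
    pairs, the notation i ↛ j meaning removal of the edge from i to j);
    ``kind="reduce_outgoing"`` uses ``node`` and the reduction fraction
    ``p`` in [0, 1].
    """

    kind: str
    edges: list[tuple[int, int]] = field(default_factory=list)
    node: int | None = None
    p: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("remove_edges", "reduce_outgoing"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.kind == "reduce_outgoing":
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"reduction fraction p must be in [0, 1], got {self.p}")
            if self.node is None:
                raise ValueError("reduce_outgoing requires a node index")
        for s, t in self.edges:
            if s == t:
                raise ValueError(f"self-edge ({s}, {t}) is not a valid removal target")
        if not self.label:
            if self.kind == "remove_edges":
                self.label = "remove " + ",".join(f"{s}->{t}" for s, t in self.edges)
            else:
                self.label = f"reduce node {self.node} by {self.p:g}"


def remove_edges(
    C: Connectome,
    edges: list[tuple[int, int]],
    norm: str = "max",
) -> Connectome:
    """Zero the listed (source, target) edges, then re-normalize.

    ``norm="max"`` (default) divides the whole matrix by its new global
    maximum so the strongest remaining weight is exactly 1; ``"sum"``
    rescales to preserve the total connective strength; ``"none"`` skips
    renormalization.
    """
    W = C.weights.copy()
    n = W.shape[0]
    for s, t in edges:
        if not (0 <= s < n and 0 <= t < n) or s == t:
            raise IndexError(f"invalid edge ({s}, {t}) for {n} nodes")
        W[t, s] = 0.0
    if norm == "max":
        top = W.max()
        if top <= 0:
            raise ValueError("edge removal left no positive weight to normalize to")
        W /= top
    elif norm == "sum":
        total_before, total_after = C.weights.sum(), W.sum()
        if total_after <= 0:
            raise ValueError("edge removal left no positive weight to normalize to")
        W *= total_before / total_after
    elif norm != "none":
        raise ValueError(f"unknown norm {norm!r}")
    out = C.copy()
    out.weights = W
    out.meta = {**C.meta, "intervention": {"kind": "remove_edges", "edges": list(map(tuple, edges)), "norm": norm}}
    return out


def reduce_outgoing(C: Connectome, node: int, p: float) -> Connectome:
    """Scale all outgoing weights of ``node`` by ``1 - p``, then rescale
    the whole matrix to preserve the initial total connective strength."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"reduction fraction p must be in [0, 1], got {p}")
    n = C.n_nodes
    if not (0 <= node < n):
        raise IndexError(f"node index {node} out of range for {n} nodes")
    W = C.weights.copy()
    total_before = W.sum()
    W[:, node] *= 1.0 - p
    total_after = W.sum()
    if total_after <= 0:
        raise ValueError("reduction left zero total connective strength")
    W *= total_before / total_after
    out = C.copy()
    out.weights = W
    out.meta = {**C.meta, "intervention": {"kind": "reduce_outgoing", "node": node, "p": p}}
    return out


def apply_intervention(C: Connectome, spec: InterventionSpec) -> Connectome:
    if spec.kind == "remove_edges":
        return remove_edges(C, spec.edges)
    return reduce_outgoing(C, spec.node, spec.p)


def intervention_report(
    before: Connectome,
    after: Connectome,
    w_lower: float | None = None,
    w_upper: float | None = None,
    atol: float = 1e-12,
) -> dict:
    """Summarize what an intervention changed.

    Lists changed matrix entries, per-node deltas of the strongest
    outgoing weight and eigenvector centrality, whether a uniform global
    rescaling was applied on top of the targeted edits, and (when the
    regime thresholds ``w_lower``/``w_upper`` are supplied) which nodes'
    strongest outgoing weight crossed them.
    """
    Wb, Wa = before.weights, after.weights
    if Wb.shape != Wa.shape:
        raise ValueError(f"shape mismatch: {Wb.shape} vs {Wa.shape}")
    n = Wb.shape[0]
    # a uniform rescaling applied on top of the targeted edits is reported
    # as a flag, not as n^2 changed entries
    both = (Wb > 0) & (Wa > 0)
    rescale = float(np.median(Wa[both] / Wb[both])) if both.any() else 1.0
    rescaled = not np.isclose(rescale, 1.0, rtol=1e-12, atol=0.0)
    diff = ~np.isclose(Wa, rescale * Wb, rtol=1e-9, atol=atol)
    changed = [(int(t), int(s)) for t, s in zip(*np.nonzero(diff))]

    mow_b = np.array([max_outgoing_weight(Wb, i) for i in range(n)])
    mow_a = np.array([max_outgoing_weight(Wa, i) for i in range(n)])

    def _eig(W: np.ndarray) -> np.ndarray:
        try:
            return eigenvector_centrality(W)
        except CentralityError:
            return np.full(n, np.nan)

    eig_b, eig_a = _eig(Wb), _eig(Wa)

    crossings = []
    for name, thr in (("w_lower", w_lower), ("w_upper", w_upper)):
        if thr is None:
            continue
        for i in range(n):
            if (mow_b[i] > thr) != (mow_a[i] > thr):
                crossings.append(
                    {"node": i, "threshold": name, "value": thr,
                     "before": float(mow_b[i]), "after": float(mow_a[i])}
                )

    return {
        "changed_entries": [
            {"target": t, "source": s, "before": float(Wb[t, s]), "after": float(Wa[t, s])}
            for t, s in changed
        ],
        "global_rescaling": rescaled,
        "rescale_factor": rescale,
        "max_out_weight_delta": (mow_a - mow_b).tolist(),
        "eig_centrality_delta": (eig_a - eig_b).tolist(),
        "threshold_crossings": crossings,
    }
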