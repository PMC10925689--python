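"""Structural connectivity matrices: load, validate, mirror, randomize, write.

Orientation convention (used by every module in this package): the weight
matrix ``W`` stores the connection from node *i* to node *j* at ``W[j, i]``
(row = target, column = source), i.e. ``W[j, i] = c_ji``.  Column ``i`` holds
the outgoing weights of node ``i``; row ``i`` holds its incoming weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Connectome",
    "ConnectomeFormatError",
    "ConnectomeValidationError",
    "read_connectome",
    "write_connectome",
    "mirror_right_hemisphere",
    "randomize_weights",
]


class ConnectomeFormatError(ValueError):
    """Raised when a connectome file cannot be parsed as a square matrix."""


class ConnectomeValidationError(ValueError):
    """Raised when a weight matrix violates a structural invariant."""


@dataclass
class Connectome:
    """A weighted, directed structural connectome.

    Parameters
    ----------
    weights
        N x N nonnegative matrix, ``weights[j, i]`` = weight of the
        connection from node ``i`` to node ``j``.  Zero diagonal (no
        self-connections).
    labels
        Unique node names, length N.
    hemisphere
        Per-node tag, ``"R"`` or ``"L"``.
    focus_nodes
        Optional named node subsets (e.g. a hippocampus-like focus
        subnetwork), mapping name -> list of node indices.
    meta
        Free-form provenance metadata (seeds, generator parameters, ...).
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    hemisphere: list[str] = field(default_factory=list)
    focus_nodes: dict[str, list[int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ConnectomeFormatError(f"weight matrix must be square, got shape {W.shape}")
        self.weights = W
        n = W.shape[0]
        if not self.labels:
            self.labels = [f"node_{i}" for i in range(n)]
        if len(self.labels) != n:
            raise ConnectomeValidationError("number of labels does not match matrix size")
        if len(set(self.labels)) != n:
            raise ConnectomeValidationError("node labels must be unique")
        if not self.hemisphere:
            # first-half/second-half convention (right hemisphere first)
            half = (n + 1) // 2
            self.hemisphere = ["R"] * half + ["L"] * (n - half)
        if len(self.hemisphere) != n:
            raise ConnectomeValidationError("hemisphere tags do not match matrix size")
        if any(h not in ("L", "R") for h in self.hemisphere):
            raise ConnectomeValidationError("hemisphere tags must be 'L' or 'R'")
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        W = self.weights
        if not np.all(np.isfinite(W)):
            raise ConnectomeValidationError("weights contain non-finite entries")
        if np.any(W < 0):
            raise ConnectomeValidationError("negative connection weight")
        if np.any(np.diagonal(W) != 0):
            raise ConnectomeValidationError("nonzero diagonal (self-connections are not allowed)")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def copy(self) -> "Connectome":
        return Connectome(
            weights=self.weights.copy(),
            labels=list(self.labels),
            hemisphere=list(self.hemisphere),
            focus_nodes={k: list(v) for k, v in self.focus_nodes.items()},
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# I/O: delimited text matrix + one-line JSON sidecar with annotations
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_connectome(
    path: str | Path,
    dialect: str | None = None,
    force_zero_diagonal: bool = False,
) -> Connectome:
    """Read a connectome from a delimited text matrix.

    The file may carry a header row and leading label column; labels are
    auto-generated when absent.  Hemisphere assignments come from the JSON
    sidecar (``<path>.json``) when present, otherwise the first half of the
    nodes is tagged ``R`` and the second half ``L``.

    Parameters
    ----------
    path
        Matrix file (CSV or TSV).
    dialect
        Delimiter; inferred from the first line when ``None``.
    force_zero_diagonal
        Zero out a nonzero diagonal instead of raising.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ConnectomeFormatError(f"{path}: empty file")
    if dialect is None:
        dialect = "\t" if ("\t" in lines[0]) else ","

    rows = [ln.split(dialect) for ln in lines]

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(tok) for tok in rows[0][1:] or rows[0])
    labels: list[str] = []
    if has_header:
        header = [tok.strip() for tok in rows[0]]
        body = rows[1:]
        has_index_col = body and not _is_number(body[0][0])
        if has_index_col:
            labels = [r[0].strip() for r in body]
            body = [r[1:] for r in body]
            if len(header) == len(body[0]) + 1:
                header = header[1:]
        else:
            labels = header if _is_number(header[0]) is False else []
    else:
        body = rows
        has_index_col = not _is_number(rows[0][0])
        if has_index_col:
            labels = [r[0].strip() for r in body]
            body = [r[1:] for r in body]

    try:
        W = np.array([[float(tok) for tok in r] for r in body], dtype=float)
    except ValueError as exc:
        raise ConnectomeFormatError(f"{path}: non-numeric matrix entry ({exc})") from None
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ConnectomeFormatError(f"{path}: matrix is not square (shape {W.shape})")

    hemisphere: list[str] = []
    focus: dict[str, list[int]] = {}
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        labels = info.get("labels", labels)
        hemisphere = info.get("hemisphere", [])
        focus = {k: list(v) for k, v in info.get("focus_nodes", {}).items()}
        meta = info.get("meta", {})

    if force_zero_diagonal:
        np.fill_diagonal(W, 0.0)
    return Connectome(W, labels=labels, hemisphere=hemisphere, focus_nodes=focus, meta=meta)


def write_connectome(C: Connectome, path: str | Path, dialect: str = ",") -> Path:
    """Write the weight matrix as delimited decimal text (17 significant
    digits, so ``read(write(C))`` round-trips bit-exactly) plus a JSON
    sidecar carrying labels, hemisphere tags and focus annotations."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in C.weights:
            fh.write(dialect.join(f"{v:.17g}" for v in row))
            fh.write("\n")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "labels": C.labels,
                "hemisphere": C.hemisphere,
                "focus_nodes": C.focus_nodes,
                "meta": C.meta,
            }
        )
        + "\n"
    )
    return path


# ---------------------------------------------------------------------------
# Mirroring and surrogate randomization
# ---------------------------------------------------------------------------

def swap_hemisphere_label(label: str) -> str:
    """Swap an ``"r "``/``"l "`` hemisphere prefix (add ``"l "`` if none)."""
    for a, b in (("r ", "l "), ("R ", "L ")):
        if label.startswith(a):
            return b + label[2:]
        if label.startswith(b):
            return a + label[2:]
    return "l " + label


def mirror_right_hemisphere(
    W_rr: np.ndarray,
    W_rl: np.ndarray,
    labels_r: list[str] | None = None,
) -> Connectome:
    """Build a two-hemisphere connectome from right-hemisphere blocks.

    The mouse connectome is laterally symmetric: the full matrix has block
    layout ``[[R-R, R-L], [L-R, L-L]]`` with ``L-L = R-R`` and
    ``L-R = R-L``.  ``W_rl`` holds the cross-hemisphere block (weights of
    connections from left-hemisphere sources to right-hemisphere targets,
    in the row=target convention); its diagonal need not be zero, since a
    region may project to its contralateral homologue.
    """
    W_rr = np.asarray(W_rr, dtype=float)
    W_rl = np.asarray(W_rl, dtype=float)
    if W_rr.shape != W_rl.shape or W_rr.ndim != 2 or W_rr.shape[0] != W_rr.shape[1]:
        raise ConnectomeFormatError(
            f"hemisphere blocks must be square and equally sized, got {W_rr.shape} and {W_rl.shape}"
        )
    n = W_rr.shape[0]
    W = np.block([[W_rr, W_rl], [W_rl, W_rr]])
    if labels_r is None:
        labels_r = [f"r node_{i}" for i in range(n)]
    labels = list(labels_r) + [swap_hemisphere_label(lab) for lab in labels_r]
    return Connectome(W, labels=labels, hemisphere=["R"] * n + ["L"] * n)


def randomize_weights(C: Connectome, rel_std: float, seed: int) -> Connectome:
    """Draw a surrogate connectome: each positive weight is replaced by a
    draw from Normal(c_ji, rel_std * c_ji); negative draws fall back to the
    original weight, zeros (and the diagonal) stay exactly zero.

    The same seed reproduces the same surrogate bit-for-bit.
    """
    if rel_std < 0:
        raise ValueError(f"rel_std must be nonnegative, got {rel_std}")
    rng = np.random.default_rng(seed)
    W = C.weights
    draws = rng.normal(loc=W, scale=rel_std * W)
    W_new = np.where(draws < 0, W, draws)
    W_new[W == 0] = 0.0
    np.fill_diagonal(W_new, 0.0)
    out = C.copy()
    out.weights = W_new
    out.meta = {**C.meta, "randomized": {"rel_std": rel_std, "seed": seed}}
    return out
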