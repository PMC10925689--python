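"""Experiment orchestration: EZ sweeps, regime thresholds, intervention
evaluation, reduction scans, and simulated functional connectivity.

Every experiment follows the same recipe: pick a single epileptogenic
node (x0 = −1.6, all others at the propagation-zone value −2.1), simulate
the coupled network, detect per-node onsets on the slow variable z, and
classify the propagation as localized or widespread.  Seeds are assigned
deterministically per (connectome, EZ) pair so that reruns — and the
level-0 row of a reduction scan versus the corresponding sweep row — are
bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import Connectome
from .detection import DetectionError, analyze_trajectory
from .epileptor import EpileptorParams, IntegrationError, simulate
from .graphmetrics import node_measures
from .interventions import InterventionSpec, apply_intervention, reduce_outgoing

__all__ = [
    "DEFAULT_SWEEP_DURATION",
    "ThresholdEstimate",
    "ez_sweep",
    "estimate_weight_thresholds",
    "evaluate_interventions",
    "reduction_scan",
    "functional_connectivity",
    "fc_similarity",
    "plot_recruitment_heatmap",
]

#: Horizon of the sweep/intervention experiments, long enough for a full
#: recruitment cascade (EZ onset, first ignition, hub avalanche,
#: periphery) on the 98-node surrogates.
DEFAULT_SWEEP_DURATION = 6000.0


def _as_dict(connectomes) -> dict[str, Connectome]:
    if isinstance(connectomes, Connectome):
        connectomes = [connectomes]
    if isinstance(connectomes, dict):
        return dict(connectomes)
    out = {}
    for i, C in enumerate(connectomes):
        out[C.meta.get("id") or f"connectome_{i}"] = C
    return out


def _seed_for(base_seed: int, ci: int, ez: int) -> int:
    return (base_seed + 100_003 * ci + 101 * ez) % (2**31 - 1)


def _default_params(params: EpileptorParams | None) -> EpileptorParams:
    if params is None:
        return EpileptorParams(duration=DEFAULT_SWEEP_DURATION)
    return params


def _run_case(C: Connectome, ez: int, params: EpileptorParams, seed: int) -> dict:
    from .epileptor import X0_EZ, X0_PZ

    x0 = np.full(C.n_nodes, X0_PZ)
    x0[ez] = X0_EZ
    run_params = params.replace(seed=seed, x0=x0)
    row = {"ez_node": ez, "seed": seed, "failed": False, "error": ""}
    try:
        traj = simulate(C, run_params)
        table = analyze_trajectory(traj, [ez])
        row.update(
            recruited_fraction=table.recruited_fraction,
            recruited_count=table.recruited_count,
            propagation_class=table.propagation_class,
        )
    except (IntegrationError, DetectionError) as exc:
        row.update(
            failed=True,
            error=str(exc),
            recruited_fraction=np.nan,
            recruited_count=-1,
            propagation_class="failed",
        )
    return row


def ez_sweep(
    connectomes,
    ez_nodes: list[int],
    params: EpileptorParams | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Simulate one seizure per (connectome, EZ node) and tabulate the
    outcome together with the EZ's graph measures.

    Returns one row per pair with the recruited fraction/count, the
    propagation class, and the EZ's strongest outgoing weight plus
    normalized out-degree, eigenvector centrality and average shortest
    path length.  A simulation or detection failure flags the row
    (``failed=True``) and the sweep continues.
    """
    params = _default_params(params)
    rows = []
    for ci, (cid, C) in enumerate(_as_dict(connectomes).items()):
        measures = node_measures(C)
        for ez in ez_nodes:
            row = {"connectome_id": cid}
            row.update(_run_case(C, ez, params, _seed_for(base_seed, ci, ez)))
            m = measures.iloc[ez]
            row.update(
                ez_max_out_weight=float(m["max_out_weight"]),
                ez_out_degree_norm=float(m["out_degree_norm"]),
                ez_eig_centrality_norm=float(m["eig_centrality_norm"]),
                ez_avg_shortest_path_norm=float(m["avg_shortest_path_norm"]),
            )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ThresholdEstimate:
    """Regime thresholds on the strongest-outgoing-weight axis.

    ``w_upper`` is the largest strongest-outgoing weight among EZs that
    produced a localized seizure; ``w_lower`` the smallest among those
    that produced a widespread one.  Above ``w_upper`` every observed EZ
    was widespread, below ``w_lower`` every observed EZ was localized;
    when ``w_lower < w_upper`` the interval between them is the mixed
    regime.  A threshold is ``None`` when its regime is absent.
    """

    w_upper: float | None
    w_lower: float | None
    n_localized: int
    n_widespread: int
    n_partial: int


def estimate_weight_thresholds(sweep: pd.DataFrame) -> ThresholdEstimate:
    """Estimate the localized/widespread weight thresholds from a sweep."""
    ok = sweep[~sweep["failed"]]
    partial = ok[ok["propagation_class"] == "partial"]
    if len(partial):
        warnings.warn(f"excluding {len(partial)} partial rows from threshold estimation")
    loc = ok[ok["propagation_class"] == "localized"]["ez_max_out_weight"]
    wide = ok[ok["propagation_class"] == "widespread"]["ez_max_out_weight"]
    w_upper = float(loc.max()) if len(loc) else None
    w_lower = float(wide.min()) if len(wide) else None
    # defining property, asserted on the input sweep itself
    if w_upper is not None:
        assert not np.any(loc > w_upper)
    if w_lower is not None:
        assert not np.any(wide < w_lower)
    return ThresholdEstimate(
        w_upper=w_upper,
        w_lower=w_lower,
        n_localized=int(len(loc)),
        n_widespread=int(len(wide)),
        n_partial=int(len(partial)),
    )


def evaluate_interventions(
    C: Connectome,
    ez: int,
    specs: list[InterventionSpec],
    params: EpileptorParams | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Rerun the seizure after each intervention (baseline first).

    Every row reports the intervention label, the recruited fraction and
    propagation class, and the EZ's strongest outgoing weight in the
    modified connectome.  All rows share the same seed, so outcome
    differences are attributable to the intervention alone.
    """
    params = _default_params(params)
    seed = _seed_for(base_seed, 0, ez)
    rows = []
    for label, Ci in [("baseline", C)] + [(s.label, apply_intervention(C, s)) for s in specs]:
        row = {"intervention": label}
        row.update(_run_case(Ci, ez, params, seed))
        row["ez_max_out_weight"] = float(Ci.weights[:, ez].max())
        rows.append(row)
    return pd.DataFrame(rows)


def reduction_scan(
    connectomes,
    ez: int,
    levels: list[float],
    params: EpileptorParams | None = None,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, float | None]:
    """Outgoing-weight reduction scan over connectomes x levels.

    Level 0.0 is always included and reproduces the corresponding
    ``ez_sweep`` row exactly (same seeds).  Returns the table and the
    minimal level that confines the seizure (localized class) on every
    connectome, or ``None`` if no scanned level does.
    """
    params = _default_params(params)
    levels = sorted(set([0.0] + [float(v) for v in levels]))
    cons = _as_dict(connectomes)
    rows = []
    for ci, (cid, C) in enumerate(cons.items()):
        seed = _seed_for(base_seed, ci, ez)
        for p in levels:
            Ci = C if p == 0.0 else reduce_outgoing(C, ez, p)
            row = {"connectome_id": cid, "level": p}
            row.update(_run_case(Ci, ez, params, seed))
            row["ez_max_out_weight"] = float(Ci.weights[:, ez].max())
            rows.append(row)
    df = pd.DataFrame(rows)
    confining = None
    for p in levels:
        sub = df[df["level"] == p]
        if len(sub) and (sub["propagation_class"] == "localized").all():
            confining = p
            break
    return df, confining


# ---------------------------------------------------------------------------
# Simulated functional connectivity
# ---------------------------------------------------------------------------

def functional_connectivity(traj, warmup: float | None = None) -> np.ndarray:
    """Pearson-correlation matrix of the per-node field-potential proxy
    (x2 − x1) over the post-warmup window.  Symmetric with unit diagonal;
    a constant-signal node gets zero off-diagonal correlations (with a
    warning)."""
    if warmup is None:
        warmup = traj.params.warmup
    mask = traj.times > warmup
    if not mask.any():
        raise ValueError("post-warmup window is empty")
    X = traj.lfp[:, mask]
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} node(s) with constant signal; correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(X)
    fc[np.isnan(fc)] = 0.0
    np.fill_diagonal(fc, 1.0)
    return fc


def fc_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of the upper triangles of two FC matrices."""
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"FC matrices must share a square shape, got {A.shape}, {B.shape}")
    iu = np.triu_indices(A.shape[0], k=1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def plot_recruitment_heatmap(
    df: pd.DataFrame,
    value: str = "recruited_fraction",
    index: str = "connectome_id",
    columns: str = "ez_node",
    path=None,
):
    """Connectome-by-case heatmap of recruited fractions (the matrix
    analogue of the recruitment-percentage panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = df.pivot_table(index=index, columns=columns, values=value)
    fig, ax = plt.subplots(figsize=(1 + 0.5 * pivot.shape[1], 1 + 0.3 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(pivot.shape[1]), [str(c) for c in pivot.columns], rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), [str(i) for i in pivot.index])
    ax.set_xlabel(columns)
    ax.set_ylabel(index)
    fig.colorbar(im, ax=ax, label=value)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
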