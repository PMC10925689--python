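"""Synthetic connectomes and toy signals with the structure the analysis assumes.

The generator emulates the gross architecture of a mirrored mouse
structural connectome so that every downstream stage is testable without
any external data:

* two mirrored hemispheres (R-R block equals L-L, R-L equals L-R);
* a three-node "hippocampus-like" focus subnetwork per hemisphere with
  strong intra-focus and cross-hemisphere edges, whose strongest
  outgoing weights are set exactly to configurable values;
* two "gateway" nodes per hemisphere (entorhinal/subiculum-like) that
  receive the focus output and project strongly onto the hub core;
* a densely and strongly interconnected hub core (a rich club) that can
  carry a recruitment cascade across the network;
* a sparse, weak, heavy-tailed (log-normal) periphery.

Weights are max-normalized to 1.  The default focus profile keeps the
shape of the mouse hippocampal one (CA1 : CA3 : DG = 0.36 : 0.18 : 0.25)
but is rescaled so the three nodes straddle this implementation's
empirical recruitment threshold, reproducing the widespread / localized
/ intermediate regime pattern (see docs/methods.md for the calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectome import Connectome, mirror_right_hemisphere, write_connectome

__all__ = [
    "SyntheticSpec",
    "make_synthetic_connectome",
    "make_onset_signal",
    "make_fixture_suite",
]

#: Allen mouse hippocampal strongest-outgoing profile (l CA1, l CA3, l DG),
#: used as the shape template for the default focus weights.
ALLEN_FOCUS_PROFILE = (0.36, 0.18, 0.25)

#: Default focus strongest-outgoing weights: the Allen profile rescaled by
#: 5/3 so the high/low/mid nodes straddle the coupled Epileptor's
#: single-pathway recruitment threshold the way CA1/CA3/DG straddle the
#: regime thresholds on the Allen matrix.
DEFAULT_FOCUS_WEIGHTS = (0.60, 0.30, 0.42)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic connectome generator.

    Core fields
    -----------
    n_per_hemisphere
        Nodes per hemisphere (>= 4: a 3-node focus plus background).
    background_weight_scale
        Log-normal median of periphery edge weights, on the scale where
        the global maximum is 1.
    density
        Fraction of nonzero periphery edges.
    focus_out_weights
        Intended strongest-outgoing weight of the three focus nodes
        (high, low, mid roles).
    focus_internal_weight
        Weight of the strong non-maximal focus edges (intra-focus,
        cross-hemisphere and focus-to-hub); per source node it is capped
        at 0.75 x that node's strongest-outgoing weight so the realized
        maximum stays exactly at its specified value.
    seed
        Generator seed; identical seeds give bit-identical connectomes.

    Hub-core fields (the rich club that carries widespread cascades)
    -----------------------------------------------------------------
    n_hubs, hub_density, hub_weight, hub_sigma
        Number of hub nodes per hemisphere and density / log-normal
        median / log-SD of hub-to-hub weights.
    hub_out_density, hub_out_weight, hub_out_sigma
        Density and weight law of hub-to-periphery projections.
    background_sigma
        Log-SD of periphery weights.
    cross_thin
        Density multiplier applied to the cross-hemisphere hub tiers
        (the weak background keeps its density in both blocks).
    focus_out_cap
        Background edges leaving a focus node are clipped to this
        fraction of its specified strongest-outgoing weight.
    """

    n_per_hemisphere: int = 49
    background_weight_scale: float = 0.05
    density: float = 0.15
    focus_out_weights: tuple[float, float, float] = DEFAULT_FOCUS_WEIGHTS
    focus_internal_weight: float = 0.45
    seed: int = 0
    n_hubs: int = 12
    hub_density: float = 0.6
    hub_weight: float = 0.65
    hub_sigma: float = 0.15
    hub_out_density: float = 0.35
    hub_out_weight: float = 0.28
    hub_out_sigma: float = 0.3
    background_sigma: float = 0.8
    cross_thin: float = 0.5
    focus_out_cap: float = 0.5
    gateway_weight: float = 0.55
    gateway_density: float = 0.9

    def __post_init__(self) -> None:
        if self.n_per_hemisphere < 4:
            raise ValueError("n_per_hemisphere must be at least 4 (3 focus nodes + background)")
        if not 0.0 < self.density <= 1.0:
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if len(self.focus_out_weights) != 3 or any(w <= 0 for w in self.focus_out_weights):
            raise ValueError("focus_out_weights must be three positive reals")
        for name in ("background_weight_scale", "focus_internal_weight", "hub_weight", "hub_out_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _tier(rng, targets, sources, density, median, sigma, shape):
    """A sparse log-normal block: mask x LogNormal(ln median, sigma)."""
    block = np.zeros(shape)
    mask = rng.random((len(targets), len(sources))) < density
    draws = rng.lognormal(np.log(median), sigma, size=mask.shape)
    sub = np.where(mask, draws, 0.0)
    block[np.ix_(targets, sources)] = sub
    return block


def make_synthetic_connectome(spec: SyntheticSpec) -> Connectome:
    """Generate a mirrored two-hemisphere connectome from ``spec``.

    The right hemisphere (and the right-from-left cross block) is drawn
    tier by tier, max-normalized to 1, the focus wiring is overwritten
    with its exact specified weights, and the result is mirrored.  Each
    focus node's realized strongest outgoing weight equals its
    ``focus_out_weights`` entry exactly; the global maximum is 1 unless a
    focus weight exceeds 1.
    """
    n = spec.n_per_hemisphere
    rng = np.random.default_rng(spec.seed)
    focus = [0, 1, 2]
    n_gateways = 2 if n >= 10 else 0
    gateways = list(range(3, 3 + n_gateways))
    n_hubs = min(spec.n_hubs, max(n - 3 - n_gateways - 1, 1))
    hubs = list(range(3 + n_gateways, 3 + n_gateways + n_hubs))
    periph = list(range(3 + n_gateways + n_hubs, n)) or hubs  # degenerate tiny nets
    all_nodes = list(range(n))

    def draw_block(thin: float) -> np.ndarray:
        # weak heavy-tailed background over every pair (cross_thin applies
        # to the strong hub tiers only, so density=1 means complete); the
        # hub tiers overwrite their own entries with the core weights
        W = _tier(rng, all_nodes, all_nodes, spec.density,
                  spec.background_weight_scale, spec.background_sigma, (n, n))
        hub_core = _tier(rng, hubs, hubs, spec.hub_density * thin,
                         spec.hub_weight, spec.hub_sigma, (n, n))
        hub_out = _tier(rng, periph, hubs, spec.hub_out_density * thin,
                        spec.hub_out_weight, spec.hub_out_sigma, (n, n))
        for tier in (hub_core, hub_out):
            W = np.where(tier > 0, tier, W)
        return W

    W_rr = draw_block(1.0)
    np.fill_diagonal(W_rr, 0.0)
    W_rl = draw_block(spec.cross_thin)

    top = max(W_rr.max(), W_rl.max())
    if top > 0:
        W_rr /= top
        W_rl /= top

    w1, w2, w3 = spec.focus_out_weights

    # background edges leaving a focus node stay well below its maximum
    for k, wk in zip(focus, (w1, w2, w3)):
        cap = spec.focus_out_cap * wk
        W_rr[:, k] = np.minimum(W_rr[:, k], cap)
        W_rl[:, k] = np.minimum(W_rl[:, k], cap)

    def internal(w_src: float) -> float:
        return min(spec.focus_internal_weight, 0.75 * w_src)

    f1, f2, f3 = focus
    # intra-focus wiring (CA1/CA3/DG roles): node 1 drives node 2 at its
    # full strongest-outgoing weight, node 3's strongest edge also targets
    # node 2, node 2 has no strong extra-focus outgoing edge
    W_rr[f2, f1] = w1
    W_rr[f3, f1] = internal(w1)
    W_rr[f1, f2] = w2
    W_rr[f3, f2] = internal(w2)
    W_rr[f2, f3] = w3
    W_rr[f1, f3] = internal(w3)
    # gateway pathway: both gateways receive the strong focus output and
    # broadcast onto the hub core (one gateway alone cannot ignite a hub;
    # the pair, driven by focus nodes 1 and 3 together, can)
    if n_gateways:
        for gw in gateways:
            W_rr[gw, f1] = internal(w1)
            W_rr[gw, f3] = internal(w3)
            for h in hubs:
                if rng.random() < spec.gateway_density:
                    W_rr[h, gw] = spec.gateway_weight
    elif len(hubs) >= 2:  # tiny nets: wire the focus straight into the hubs
        W_rr[hubs[0], f1] = internal(w1)
        W_rr[hubs[0], f3] = internal(w3)
        W_rr[hubs[1], f1] = internal(w1)
    # cross-hemisphere focus wiring (strong inter-hippocampal edges)
    W_rl[f2, f1] = internal(w1)
    W_rl[f3, f3] = internal(w3)

    labels = (
        [f"r hip{k + 1}" for k in range(3)]
        + [f"r gw{k:02d}" for k in gateways]
        + [f"r hub{k:02d}" for k in hubs]
        + [f"r n{k:02d}" for k in periph]
    )[:n]
    C = mirror_right_hemisphere(W_rr, W_rl, labels_r=labels)
    C.focus_nodes = {"right_focus": [0, 1, 2], "left_focus": [n, n + 1, n + 2]}
    C.meta = {
        "id": f"synthetic[n={2 * n},seed={spec.seed}]",
        "generator": "epiprop.synthetic.make_synthetic_connectome",
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(spec).items()},
    }

    # contract: realized strongest outgoing weight of each focus node is
    # exactly the specified value (both hemispheres, by mirror symmetry)
    for k, wk in zip((0, 1, 2), (w1, w2, w3)):
        for node in (k, n + k):
            realized = C.weights[:, node].max()
            if realized != wk:
                raise AssertionError(
                    f"focus node {node}: realized max outgoing {realized} != spec {wk}"
                )
    return C


def make_onset_signal(
    n_nodes: int,
    onset_times: list[float | None],
    duration: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    slope: float = 1.0,
    baseline: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise test signal for the onset detector: flat baseline plus
    Gaussian noise, rising linearly (slope >> noise) after each node's
    onset time; nodes with a ``None`` onset stay at baseline.

    Returns ``(signal, times)`` with signal shape (n_nodes, samples).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if len(onset_times) != n_nodes:
        raise ValueError("need one onset time (or None) per node")
    times = np.arange(0.0, duration + dt / 2, dt)
    rng = np.random.default_rng(seed)
    sig = baseline + noise_sd * rng.standard_normal((n_nodes, len(times)))
    for i, t_on in enumerate(onset_times):
        if t_on is None:
            continue
        if not 0 <= t_on <= duration:
            raise ValueError(f"onset time {t_on} outside [0, {duration}]")
        ramp = np.clip(times - t_on, 0.0, None) * slope
        sig[i] += ramp
    return sig, times


def make_fixture_suite(seed: int = 0, out_dir: str | Path | None = None) -> dict[str, Connectome]:
    """The named fixture connectomes used throughout the test-suite.

    * ``toy10`` — 10-node mirrored net for graph-measure oracle tests;
    * ``two_hemi20`` — 20-node net with the focus triplet;
    * ``surrogate98`` — 98-node mouse-shaped surrogate (49 per
      hemisphere, focus triplet, hub core).

    When ``out_dir`` is given, each connectome is also written there as
    delimited text plus its JSON sidecar.
    """
    suite = {
        "toy10": make_synthetic_connectome(
            SyntheticSpec(n_per_hemisphere=5, n_hubs=1, density=0.6, seed=seed)
        ),
        "two_hemi20": make_synthetic_connectome(
            SyntheticSpec(n_per_hemisphere=10, n_hubs=4, density=0.3, seed=seed + 1)
        ),
        "surrogate98": make_synthetic_connectome(SyntheticSpec(seed=seed + 2)),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, C in suite.items():
            write_connectome(C, out_dir / f"{name}.csv")
    return suite
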