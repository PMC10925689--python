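# Methods

## Model

Each brain region is a six-variable Epileptor with the standard
parameters I₁ = 3.1, I₂ = 0.45, r = 8·10⁻⁵, K = 0.2, τ = 10,
σ = 0.0025.  The fast nonlinearity uses the canonical cubic branch
f₁ = x₁³ − 3x₁² for x₁ < 0 and (x₂ − 0.6(z − 4)²)x₁ for x₁ ≥ 0; the
sharp-wave drive is f₂ = 0 below x₂ = −0.25 and 6(x₂ + 0.25) above.
Time is dimensionless ("model time units") throughout: we make no claim
about a mapping to seconds, and all horizons are configurable.

**Coupling.** Regions interact only through permittivity coupling in
the slow equation, over incoming connections and inside the
slow-timescale bracket:

    ż_i = r (4(x₁,ᵢ − x₀,ᵢ) − z_i [− 0.1 z_i⁷ if z_i < 0] + K Σ_j w(j→i)(x₁,ᵢ − x₁,ⱼ)).

Placing the coupling inside the r-bracket is essential: applied outside
it the coupling overwhelms the slow dynamics by three orders of
magnitude, every connected node is recruited instantly, and no
localized/widespread dichotomy can exist.  Inside the bracket the
mechanism is a slow race — a seizing neighbour's elevated x₁ drags z_i
toward the saddle-node at z_SN = 2.914 against a restoring force whose
maximum is 4(x₀c − x₀) — which is exactly what produces weight
thresholds for recruitment.

**Critical epileptogenicity.** On the interictal branch the resting
state sits at the root of x₁³ + 2x₁² + (1 + I₁) = z with
z = 4(x₁ − x₀); the branch folds at x₁ = −4/3, giving
x₀c = −4/3 − z_SN/4 ≈ −2.0618 analytically.  The bisection in
`find_critical_x0` (simulation + onset detection, tolerance 0.01)
returns −2.059, an independent numerical confirmation of both the
integrator and the detector.

**Integration.** Stochastic Heun (predictor–corrector), dt = 0.05,
additive noise of SD σ·√dt per step on the x₂ and y₂ updates only,
shared between predictor and corrector.  The optional numba kernel and
the numpy reference path are asserted equal to 1e-10 in the tests.
Output is sampled every 10 steps (0.5 time units).  Non-finite states
abort with the blow-up time.

**Initial conditions.** All nodes start at the interictal fixed point of
the fast subsystem with z frozen at 4(x₁* − x₀) evaluated at the
propagation-zone epileptogenicity (z ≈ 2.918), plus a seeded uniform
jitter of 10⁻³.  Healthy nodes (x₀ = −2.1) thus sit on their stable
branch from t = 0 — their z is then deterministic, because the injected
noise enters x₂/y₂ which feed back into x₁ only during ictal phases —
while an EZ node's z decays toward its own (nonexistent) equilibrium and
crosses the saddle-node within a few hundred time units.  This choice
makes onset latencies short and classifications horizon-stable; warmup
defaults to 15 time units with the onset-detector baseline taken from
the 10 units before it.

## Onset detection

"z starts increasing" is operationalized as: baseline mean μ and SD s
over [warmup − 10, warmup]; onset is the first t > warmup at which the
smoothed z (centred moving average over 11 samples) exceeds
μ + max(0.05, 5s) and keeps non-decreasing for 1 time unit.  The
absolute floor of 0.05 dominates in practice (baseline z is nearly
noise-free, see above); it introduces a uniform detection lag of
~100–150 time units after the true saddle-node crossing which cancels in
the time distances T_i.  All knobs are exposed; the defaults were set
against constructed flat-then-ramp signals (exact recovery without
noise, ±5 units under noise across 50 seeded fixtures).

Classification: localized ≤ 2 recruited non-EZ regions; widespread ≥
50 % of them; "partial" is retained as a safety valve but does not occur
in practice — observed recruited fractions cluster at 0 and ~1.

## Graph measures

Row = target, column = source everywhere (`W[j, i]` = weight i→j).
Out-degree is a column sum, in-degree a row sum.  Eigenvector centrality
uses the outgoing-influence orientation (a node is central when the
nodes it projects to are central), computed by power iteration on
I + Wᵀ — the identity shift guarantees convergence for matrices whose
extremal eigenvalues come in ±λ pairs (pure 2-cycles); acyclic matrices
are rejected upfront (leading eigenvalue 0).  A `direction="in"` switch
is provided.  Path lengths invert weights as l_ji = c_m − c_ji with c_m
the global maximum, applied to *every* ordered pair (zero-weight pairs
become maximal-length edges, making the graph complete); per-node
averages divide by N with l_ii = 0 included.  Degrees, paths and
strongest-outgoing weights are verified against exhaustive brute-force
oracles on ≥ 100 random matrices up to 6 nodes.

## Interventions

*Edge removal* zeroes the listed (source → target) entries and then
re-normalizes the global maximum back to 1 (config: `max`, `sum` or
`none`; max-normalization keeps intervened and baseline weights on the
same scale as the regime thresholds).  *Outgoing-weight reduction*
multiplies a node's outgoing weights by 1 − p and rescales the whole
matrix to preserve the grand total of connective strength exactly
(checked to 1e-12 relative).  Both are pure functions preserving shape,
nonnegativity, zero diagonal and zero entries.

## Synthetic connectome generator

The generator emulates the gross architecture of a mirrored mouse
connectome rather than any specific matrix: one hemisphere is drawn and
mirrored (R-R = L-L, R-L = L-R), weights are max-normalized to 1, and
four node classes are wired per hemisphere —

* **focus triplet** (hippocampus-like, CA1/CA3/DG roles): node 1's
  strongest edge targets node 2; node 3's strongest edge also targets
  node 2; node 2 has no strong extra-focus outgoing edge; strong
  cross-hemisphere edges mirror the inter-hippocampal projections.  Each
  focus node's realized strongest outgoing weight equals its specified
  value exactly (non-maximal strong edges are capped at 0.75× the
  node's maximum, background edges leaving a focus node at 0.5×).
* **gateways** (entorhinal/subiculum-like): two low-in-degree nodes that
  receive the focus output and broadcast (weight 0.55, density 0.9) onto
  the hubs.  One gateway alone cannot ignite a hub; the pair — driven by
  focus nodes 1 and 3 together — can.
* **hub core** (rich club): 12 nodes, hub–hub density 0.6 with
  log-normal weights (median 0.65), projecting to the periphery
  (density 0.35, median 0.28).
* **periphery**: sparse (density 0.15), weak, heavy-tailed log-normal
  background (median 0.05, log-SD 0.8) over all pairs.

**Calibration.** The recruitment threshold of this implementation was
measured directly (two-node sweep: a single edge from a seizing to a
healthy node recruits it from w ≈ 0.47; slightly higher in networks,
where a seizing node's incoming diffusive coupling shortens its own
seizure).  The default focus profile (0.60, 0.30, 0.42) is the mouse
hippocampal profile (0.36, 0.18, 0.25) scaled by 5/3 so that the three
nodes straddle this threshold the way CA1/CA3/DG straddle the regime
band on the Allen matrix: high → widespread, low → localized, mid →
near-threshold.  The absolute band position is a property of the
specific connectome and of unpublished details of the original
simulation configuration; the reproduced object is the regime
*structure*, not the band's absolute location.  These defaults were
fixed from the two-node measurement before the acceptance checks were
written and are not tuned per test.

**What the surrogate does and does not show.** Passing the regime and
intervention tests on surrogates demonstrates the mechanism — threshold
recruitment keyed on the EZ's strongest outgoing weight, cascade through
a hub core, confinement by removing the single super-threshold edge or
by ≥ 20 % outgoing reduction — under a realistic architecture.  It does
not certify the Allen-specific numbers (0.36/0.18/0.25 weights,
0.31/0.22 thresholds, 40 % confinement level), which require the
external matrix and are covered by optional integration tests.  The
surrogate is also denser in mid-range weights than a real connectome (a
98-node network needs a percolating strong core that a 10⁴-edge
multi-decade weight distribution provides naturally).

**Randomized surrogates.** `randomize_weights` redraws each positive
weight from Normal(c, 0.1c) (negative draws fall back to the original),
as used for the ±10 % connectome ensembles.  A known limitation: when a
draw pushes the EZ's strongest edge near the recruitment threshold,
first ignition is delayed and the cascade can lose the co-seizing
coincidence it needs at the gateways, flipping a widespread case to
localized (observed in ~1 of 6 ensembles) — the same seed-dependent
regime flipping the mixed band exhibits on real connectomes.

## Experiment horizons and problem sizes

Sweeps and intervention evaluations default to 6000-unit horizons
(≈ EZ onset ~400, first ignition ~700, hub avalanche and periphery
recruitment within ~2000 more); the single-node bisection uses
3000-unit horizons near criticality, where the saddle-node bottleneck
passage takes ~600–800 units.  The acceptance suite runs 5 independent
98-node surrogates for the regime property plus a 4-point focus-weight
sweep and a 4-point reduction scan; all seeds are fixed and recorded in
the tables, and a full rerun is bit-identical.

## Known limitations

* No transmission delays or tract lengths; no parameter fitting; no
  alternative Epileptor variants.
* The coupled system is simulated with a fixed dt = 0.05; halving dt
  shifts onset times by far less than the detection lag but is not
  asserted beyond the single-node level.
* Functional connectivity uses the full post-warmup window including
  ictal periods; pre/post-intervention FC comparison is provided as a
  similarity score (Pearson over upper triangles) without a significance
  model.
* Multi-node EZs are supported by the API (earliest-onset reference for
  T_i) but all reference experiments use single-node EZs.
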