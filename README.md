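# epiprop

Seizure propagation and virtual interventions in whole-brain Epileptor
networks on structural connectomes.

`epiprop` is for computational neuroscientists who want to ask, in
silico: *if a seizure starts in this brain region, will it stay focal or
generalize — and what is the smallest structural intervention that keeps
it confined?*  It simulates networks of coupled Epileptor neural-mass
units on a weighted, directed structural connectome (the mouse-brain
setting: two mirrored hemispheres, a hippocampal seizure focus), detects
per-node seizure onsets, relates the propagation regime to graph
measures of the epileptogenic zone (EZ), and evaluates two
confinement strategies: targeted edge removal (virtual resection) and
outgoing-weight reduction (drug/neuromodulation-like suppression).

## The model

Each region *i* is a six-variable Epileptor — a fast discharging
subsystem (x₁, y₁), a sharp-wave subsystem (x₂, y₂) with a low-pass
variable *g*, and a slow permittivity variable *z* that gates seizure
onset and offset.  Regions interact through permittivity coupling on the
slow equation; for the z < 0 branch,

    ż_i = r ( 4(x₁,ᵢ − x₀,ᵢ) − z_i − 0.1 z_i⁷ + K Σ_j c_ji (x₁,ᵢ − x₁,ⱼ) ),

with c_ji the structural weight of the connection from *i* to *j* read
over node *i*'s incoming edges, r = 8·10⁻⁵, K = 0.2, I₁ = 3.1,
I₂ = 0.45, τ = 10, and additive Gaussian noise (σ = 0.0025) on the x₂
and y₂ equations only.  A node's excitability is set by its
epileptogenicity x₀: the EZ is placed at x₀ = −1.6 (spontaneously
seizing), all other nodes at the propagation-zone value x₀ = −2.1.  The
critical value separating the two behaviours sits at x₀c ≈ −2.06: a
seizing neighbour's elevated x₁ slowly drags a healthy node's *z* down
toward the saddle-node where its resting state disappears, which is how
seizures recruit new territory.  Whether that recruitment cascades
through the whole network or dies out is governed largely by the EZ's
strongest outgoing connection weight — the package's central statistic.

Per-node seizure onset T_onset,i is the time at which *z* starts
increasing (baseline-plus-threshold crossing with a persistence
requirement), and propagation is summarized by time distances
T_i = T_onset,i − T_onset,EZ (0 at the EZ, null when never recruited)
and classified as *localized* (at most two recruited regions) or
*widespread* (at least half the network).

Graph measures follow the weighted-digraph conventions: out/in-degree
(total outgoing/incoming strength), eigenvector centrality (power
iteration, outgoing-influence orientation), and average shortest path
length on the inverted-weight complete graph with edge lengths
l_ji = c_m − c_ji (Dijkstra), all max-normalized across nodes.

## Worked example

```python
import numpy as np
from epiprop import (SyntheticSpec, make_synthetic_connectome, EpileptorParams,
                     simulate, analyze_trajectory, remove_edges, node_measures)

# a 98-node, two-hemisphere surrogate connectome with a hippocampus-like
# three-node focus whose strongest outgoing weights are set exactly
C = make_synthetic_connectome(SyntheticSpec(seed=0))
print(node_measures(C).loc[[0, 1, 2], ["label", "max_out_weight", "eig_centrality_norm"]])

params = EpileptorParams.for_network(C.n_nodes, ez_nodes=[0], duration=6000, seed=42)
table = analyze_trajectory(simulate(C, params), ez_nodes=[0])
print(f"EZ = {C.labels[0]}: {table.propagation_class}, "
      f"{table.recruited_count}/97 regions recruited "
      f"(first recruit at +{np.nanmin(table.time_distance[1:]):.0f} time units)")

confined = analyze_trajectory(simulate(remove_edges(C, [(0, 1)]), params), ez_nodes=[0])
print(f"after removing the strongest outgoing edge: {confined.propagation_class}, "
      f"{confined.recruited_count}/97 recruited")
```

prints

```
 label  max_out_weight  eig_centrality_norm
r hip1            0.60             0.072802
r hip2            0.30             0.012600
r hip3            0.42             0.064280
EZ = r hip1: widespread, 97/97 regions recruited (first recruit at +830 time units)
after removing the strongest outgoing edge: localized, 0/97 recruited
```

A seizure started in the high-weight focus node recruits the entire
network; started in the low-weight node (`ez_nodes=[1]`) it stays fully
localized; and deleting the single strongest outgoing edge of the EZ —
its only super-threshold pathway — confines the seizure completely while
leaving the rest of the connectome untouched.  `reduce_outgoing(C, 0, p)`
achieves the same confinement from p ≈ 0.2 upward while preserving the
total connective strength.

The same workflow is scriptable from a shell via the `epiprop` command
(`synth`, `simulate`, `measure`, `intervene`, `sweep`, `thresholds`,
`reduce-scan`, `fc`); see `epiprop --help`.

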