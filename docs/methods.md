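# Methods

This note documents the models, conventions and design choices behind
`commlesion`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Networks and containers

A connectome is a symmetric non-negative weight matrix `W` with zero
diagonal over labelled parcels, each tagged `L`/`R`/`other`, optionally
with 3-D coordinates (mm) and node sizes (voxels). Input matrices whose
asymmetry exceeds a relative tolerance of `1e-8` are rejected; smaller
asymmetries are averaged. The binary adjacency is `A[i,j] = 1` iff
`W[i,j] > 0`. A cohort is a list of subjects with two scans each — the
test–retest design the longitudinal analyses require. Node indexing is
0-based in the API; all written tables carry 1-based indices next to the
labels.

Two derived networks matter downstream:

* **Node-size correction.** Tractography connectivity indices scale with
  parcel size, so `W'[i,j] = W[i,j] / (size_i + size_j)` is offered. The
  divisor is a hook (`apply_node_size_correction(..., divisor=f)`); the
  sum is the default because it is symmetric and preserves the edge rank
  order when sizes are equal.
* **Group-average network.** An edge survives iff present in ≥ 75% (the
  conventional consistency threshold, configurable) of the selected
  scans; its weight is the mean over the scans where it is present.
  Averaging over *all* scans instead is available
  (`weight_mode="all"`) but shrinks weights of borderline edges by the
  absence count, which mixes presence and magnitude information.

## Communicability

`Cm = exp(A)` counts walks of all lengths with `1/k!` down-weighting.
The weighted form `Cm^w = exp(S^{-1/2} W S^{-1/2})` uses the diagonal
strength matrix `S`; this normalization makes `Cm^w` invariant under
global weight rescaling (the test suite checks this to `1e-10`) and tames
high-strength nodes. Isolated nodes get `1/√s := 0`, so they keep a unit
diagonal and zero rows rather than raising — lesion simulations routinely
create them mid-run. Off-diagonal entries between different connected
components are pinned to exactly zero after the Padé evaluation (the
exponential of a block-diagonal matrix is block diagonal; the pinning
protects that identity from round-off).

Node-level communicability is the off-diagonal row sum. Where the lesion
analyses need a *binary* node-level communicability, the
degree-normalized form `exp(D A D)` is used, because raw `exp(A)` is
dominated by overall density.

### Communicability centrality

For node r, the lesioned matrix is the original with row and column r
zeroed — walk-equivalent, for all retained pairs, to deleting the node,
while keeping the matrix size fixed. Then

    CBC[r] = (1/K) Σ_{i≠j, i,j≠r, Cm[i,j]>0} (Cm[i,j] − Cm_r[i,j]) / Cm[i,j]

with `K` the number of ordered pairs in the sum. Pairs with
`Cm[i,j] = 0` (different components) carry no information about r and are
excluded from both sum and K. Because zeroing rows of a non-negative
matrix can only remove walks, `Cm_r ≤ Cm` entrywise and every ratio — and
hence CBC — lies in `[0, 1]`. Differences are floored at 0 and ratios
capped at 1 purely as a floating-point guard on that exact identity.

Two readings of the definition were open:

* **Relative vs absolute reduction.** The relative (ratio) form is the
  default because it is the only reading for which the `[0, 1]` bound
  holds; the absolute reduction is available via `relative=False` for
  sensitivity checks.
* **Weighted CBC normalization.** The lesioned exponential uses the
  *intact* strength normalization by default. Recomputing `S` on the
  lesioned network looks closer to "the network without node r", but it
  can *raise* the remaining normalized weights (removing a strong
  neighbour shrinks the divisor `√(s_i s_j)`) and push CBC below 0 — a
  three-node counterexample with weights 10 and 0.1 suffices. Since the
  `[0, 1]` bound is the property that makes CBC values comparable across
  networks, fixed normalization is the default and recomputation is an
  explicit option (`recompute_normalization=True`).

## Standard metrics

Weighted shortest paths use edge lengths `l = 1/w`, the standard
convention for connectivity-index weights. Betweenness is unnormalized
Brandes betweenness with fractional credit over equally short paths
(via networkx); distances use scipy's csgraph Dijkstra. Global efficiency
is the mean inverse distance over ordered pairs with `1/∞ = 0`;
characteristic path length is the mean over *finite* pairs, reported
together with the disconnected-pair fraction (efficiency, not CPL, is the
primary global metric precisely because lesioned networks disconnect).
Hubs are nodes with degree at least one *sample* (n − 1) standard
deviation above the mean; in a regular graph the SD is zero and all nodes
meet the `≥` rule. All top-k and max-criterion selections break ties
toward the lower node index, making every simulation deterministic.

## Lesion simulations

**Targeted attacks** delete whole nodes (rows/columns removed, network
shrinks) in order of one of the eight criteria (Deg, S^w, BC, BC^w, Cm,
Cm^w, CBC, CBC^w). `single_choice` recomputes the criterion on the
current network before each removal; `hubs_order` freezes the ranking on
the intact network. Binary and weighted efficiency are recorded after
every removal (index 0 = intact). If the criterion becomes undefined
(fewer than 3 nodes for CBC, empty network), the trace is truncated and
flagged rather than padded.

**Small perturbations** keep all nodes:

* binary node lesion: exactly `round(R · deg)` of the node's edges
  (half-away-from-zero rounding, floor of one edge) deleted uniformly at
  random;
* weighted node lesion: all incident weights scaled by `1 − R`
  (topology, and hence every binary metric, unchanged for `R < 1`);
* edge lesion: single uniformly chosen edges removed sequentially, the
  ordered list logged so any intermediate network can be rebuilt.

Target selection supports hub targets shared across subjects (hubs of the
cohort-average network restricted to one hemisphere, ordered by
descending degree, with N defaulting to the floored median per-subject
hub count of that hemisphere), shared random draws, independent
per-subject draws, and fixed lists. The shared hub list comes from the
average network because per-subject hub sets differ while the protocol
requires identical targets for every subject.

**Longitudinal design.** Per subject, a seeded coin flip designates one
scan as baseline; the other receives the cumulative lesion sequence, and
the state after every step is retained for the statistics layer.
Repetitions rerun the whole procedure with fresh flips and draws.

**Stroke preset.** Node lesions at "Left-Thalamus" and "Left-Caudate"
(configurable labels), per-subject rate drawn uniformly from
`[0.2, 0.8]` — the same R range as the perturbation analyses; the source
protocol states only that the rate was randomized — repeated 10 times.
Metric values are averaged over the repetitions *before* the paired
comparisons ("results were averaged"), unlike the 25-repetition
perturbation analyses, which test per repetition and then average the
significance counts (test-then-average); both orders are available
through the underlying primitives.

**Randomness.** Every draw comes from a labelled stream derived from the
root seed via `SeedSequence(root, crc32(label)...)`
(`commlesion._rng.stream`), so (seed, label) fixes the draw regardless of
call order, per-subject streams are independent, and the logs suffice for
exact replay. Experiment bundles embed the resolved config and seed;
reruns are byte-identical (timings go to a separate `run_log.json`).

## Statistics

* **Permutation test on decay curves**: statistic
  `T = Σ_steps (mean_a − mean_b)`; since T is linear in the curves it
  reduces to the difference in group means of per-curve step sums, which
  is what gets permuted. Two-sided via `|T|`;
  `p = (#{|T_perm| ≥ |T_obs|} + 1) / (n_perm + 1)` with 5000 permutations
  by default — the +1/+1 convention keeps p valid and strictly positive.
* **Paired t-tests per node**, two-sided, across subjects. Zero-variance
  differences: all-zero differences give `t = 0, p = 1` (nothing
  happened); identical non-zero differences give a flagged `±∞ / p = 0`
  sentinel (an exact, deterministic effect — binary metrics under binary
  lesions with shared targets can produce this).
* **FDR**: Benjamini–Hochberg step-up (statsmodels), family = the nodes
  of one metric at one lesion step; corrected threshold α = 0.05. The
  family definition is configurable by calling the primitives directly.
* **Distance correlations**: per-node change (baseline − lesioned, so
  positive = reduction) against hop, `1/w`-path, or Euclidean distance to
  the nearest lesion site, lesion sites excluded. Spearman for the
  ordinal hop distance, Pearson for the continuous weighted distance —
  both are always computable. Constant inputs return an explicit `None`
  sentinel instead of NaN. Tables report per-subject coefficients
  (mean ± SD) and the coefficient of the subject-averaged change against
  the subject-averaged distance.

## Synthetic cohorts

Coordinates form two lateralized Gaussian clusters (±32 mm, 18 mm
spread). A group backbone draws each edge once with probability
`∝ exp(−d/45 mm)`, boosted multiplicatively at designated hubs (default
12% of nodes at 2.5×, balanced over hemispheres) and calibrated by
bisection — under the 0.95 probability cap — so the expected density
splits a 0.25 total between intra- and inter-hemispheric pairs (15%
inter). Backbone components, if several, are joined by random bridging
edges so path metrics are defined. Edge weights are log-normal (σ = 1),
giving the right-skewed distribution connectivity indices show.

Each subject keeps a backbone edge with probability 0.9 and perturbs its
log-weight (σ = 0.3). Each *scan* is then an independent realization of
the subject's latent network: multiplicative log-normal noise with unit
mean (`exp(N(−σ²/2, σ²))`, σ = 0.15) and a 2% per-edge presence jitter.
Generating both scans symmetrically from the latent network (rather than
deriving scan B from scan A) makes the two scans exchangeable, so
baseline group comparisons are null *by construction* — the property the
longitudinal analyses assume of test-retest data. With noise and jitter
at zero both scans equal the latent network exactly.

Defaults (19 subjects, 86 regions) mirror a whole-brain test-retest DWI
cohort at the coarser of the two common FreeSurfer parcellation sizes,
which keeps communicability recomputation affordable in the simulation
loops.

`inject_distance_decaying_effect` plants ground truth for recovery tests:
damage level `f_i = amplitude · exp(−decay · d_i)` (hop distance to the
nearest focus node), each scan-B edge deleted with probability
`1 − (1 − f_i)(1 − f_j)` and otherwise scaled by `(1 − f_i)(1 − f_j)`.
Deleting edges as well as scaling them is deliberate: purely weighted
damage would leave every binary metric (Deg, Cm, CBC) exactly unchanged,
and the injected effect is meant to be recoverable through binary and
weighted metrics alike.

What the generator does *not* emulate: spatially correlated tractography
errors, distance-dependent weight magnitudes, rich-club ordering beyond
the planted hubs, and any reorganization after damage. Passing recovery
tests therefore show that the statistical machinery detects the modelled
effects at realistic noise levels — not that real lesions behave like the
model.

## Problem sizes and numerical choices

The heavy primitive is one matrix exponential per node per network for
CBC (O(n⁴) per network). The simulation-based checks therefore run at
moderated scales chosen as representative rather than exhaustive:
attack-strategy comparisons on 15-subject, 60-node cohorts with 30
removals; distance-recovery on the same size over 50 seeds with amplitude
0.5 and decay rate 1.0; baseline equivalence on the full 19 × 86 default
over 100 seeds; bound checks on 200 random connected graphs of 10–60
nodes. Closed-form oracles (single edge `sinh 1`, K3
`(e² − e⁻¹)/3`, normalized K3 `(e − e^{−1/2})/3`, star-center and
path-middle CBC = 1, Eff(P3) = 5/6) are asserted to `1e-9`; brute-force
oracles (truncated walk series, exhaustive shortest-path enumeration,
sort-and-cumulative-min BH, exact permutation enumeration) cover the same
code paths on tiny inputs.

## Known limitations

* CBC is recomputed by dense `expm` per node; networks beyond a few
  hundred nodes call for low-rank update schemes not implemented here.
* The permutation test treats curves as exchangeable units; with very few
  subjects the discrete null limits attainable p-values.
* The weighted-CBC normalization choice (fixed vs recomputed) changes
  values, not usually rankings; both are exposed, only the bounded
  variant is default.
* Characteristic path length on disconnected networks is a conditional
  mean; compare networks via efficiency when lesions fragment them.
* No visualization: outputs are tables keyed by labels and 1-based
  indices, intended for downstream plotting tools.
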