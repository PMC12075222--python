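# Methods

## Problem and model

`chronosta` addresses supertree construction for *timetrees*: rooted
phylogenies whose branch lengths are in absolute time, so that every node
has an age and every extant tip sits at age 0. The input is a collection of
such trees with partially overlapping leaf sets; the output is one
ultrametric supertree over the union of taxa, with an age at every node.

The method is agglomerative clustering on divergence times. An ultrametric
tree is equivalent to an ultrametric matrix (for every leaf triple, the
largest pairwise MRCA age is attained at least twice), so if the full
taxon-pair age matrix were known, average-linkage clustering would
reconstruct the tree directly. The difficulty is sparsity: in realistic
collections most taxon pairs never co-occur in any tree, so most cells of
the consensus matrix are missing and plain UPGMA cannot run. The assembly
closes the gaps by *backpropagation*: after each globally-minimal pair is
clustered, the cluster replaces its members inside every per-tree matrix,
inheriting their distances as member-weighted means. A tree containing only
one member of the pair thereby acquires a usable row for the whole cluster,
and subsequent consensus matrices contain divergence times for pairs of
taxa that never co-occurred. No statistical imputation is involved — every
filled cell traces back to observed divergence times through the
sister-taxa identity (two sister clades are equally related to any third).

Key semantic choices:

- **Ages, not patristic distances.** On ultrametric trees the patristic
  distance is twice the MRCA age; matrices and merge heights here are in
  age units throughout, since node age is the quantity being integrated.
- **The supermatrix is recomputed from the updated per-tree matrices at
  every iteration** rather than updated in place. The two disagree when a
  cell's support changes (a cluster consolidates two trees' evidence);
  recomputation is what makes backpropagation informative.
- **Member counts in the weighted update are global cluster sizes** (leaf
  counts of the recorded clusters), not per-matrix counts, matching the
  definition *n_ij = n_i + n_j* of the cluster being recorded.
- **Merge ages come from the consensus supermatrix.** The within-tree age
  of a merged pair observed in an individual matrix is logged (it can be
  inspected via `ChronoStaResult.stored_pair_log`) but does not override
  the consensus mean.
- **Tie-breaking** for equal minimum distances orders candidates by the
  sorted list of member leaves, making runs platform-independent. The
  choice is arbitrary but fixed.
- Cluster ids are synthesized as `C<iteration>`; leaf labels are never
  reused.

After the final merge, the recorded clusters define a complete matrix (the
age of a pair is the merge age of the first cluster containing both) and
the supertree is rebuilt from it by classical UPGMA with heights equal to
matrix values. When the recorded merge ages are monotone increasing — the
usual case — this reproduces the merge sequence exactly (a unit test
asserts the coincidence); when noise makes recorded ages non-monotone, the
average-linkage pass and the subsequent smoothing resolve the conflicts.

## Ultrametric smoothing

Conflicting inputs can leave a parent node younger than a child. The final
(and any perturbed) tree is projected onto the feasible set by minimising
`sum_v (a_v - observed_v)^2` over internal-node ages subject to
`a_parent >= a_child` on every edge and all tips fixed at age 0 — i.e. all
implied branch durations are non-negative. This is a small strictly convex
quadratic program with a unique solution; it is solved with an
interior-point method (`scipy.optimize.minimize(method="trust-constr")`,
with an always-feasible running-maximum start), followed by an exact
refinement that pools nodes joined by active constraints to the mean of
their observations (the KKT characterisation of the optimum), accepted only
if feasible and no worse. Feasible inputs are returned unchanged. Tests
check the objective against an independent SLSQP solve and closed-form
pooled-mean cases; agreement is required to 1e-6.

Age comparisons elsewhere use an absolute tolerance of 1e-9 scaled by the
collection's maximum root age.

## Evaluation metrics

- **nRF** = RF / (2(m − 3)), where RF counts non-trivial unrooted
  bipartitions present in exactly one tree and m is the number of shared
  species (both trees are pruned to the shared set first; nRF is defined as
  0 for m ≤ 3).
- **Polytomy-aware nRF** counts a split as an error only if it is
  *incompatible* with the other tree (some split there crosses it), so a
  binary resolution of a polytomy is not penalised; normalisation is by the
  total number of non-trivial splits across both trees, which reduces to
  2(m − 3) for binary-vs-binary. This compatibility-based reading is one
  standard polytomy-aware variant; the normalisation is reported with the
  value for transparency.
- **Node-age agreement** maps every reference internal node to the inferred
  age of the MRCA of its descendant set (even where topologies disagree;
  nodes with descendants absent from the inferred tree are skipped and
  counted). Slope is the least-squares fit through the origin,
  `slope = Σ t_ref·t_est / Σ t_ref²`; R² uses the uncentered definition
  `1 − SS_res / Σ t_est²`, the standard choice for no-intercept fits.
  ΔTE_v = 100·(t_est − t_ref)/t_ref, with the median reported.

## Synthetic collections

The generator emulates the sparsity structure of multi-study timetree
corpora directly at the tree level, replacing sequence simulation, ML
inference and relaxed-clock dating with age perturbation:

- **Model tree:** pure-birth (Yule) with n = 51 leaves by default, rescaled
  to root age 455 (Ma scale, a vertebrate-depth radiation). Internal ages
  are almost surely distinct.
- **Constituent trees:** the model's leaves are partitioned into clades
  (splitting the largest clade until blocks are small, then balancing
  blocks into five groups); each of five trees is the model restricted to
  one group plus ~6% of taxa bridging to the next group, and a sixth
  backbone tree samples two taxa per group. Defaults yield ≈75% of species
  missing per tree (within the published 67–88% per-tree range), with ≈71%
  of species present in exactly one clade-restricted tree. Bridges plus the
  backbone guarantee a connected co-occurrence graph, and every model
  node's age is witnessed by at least one cross-clade pair, so noiseless
  collections are exactly recoverable.
- **Noise:** every internal age is multiplied by an independent lognormal
  factor with log-sd σ√(1 + k); the baseline σ = 0.05 (≈5% age error)
  stands in for dating error, and the variance-inflation factor k adds k
  times the baseline log-scale variance (k = 3 gives log-sd 0.10),
  emulating increasingly uncertain constituent node times. Perturbed trees
  are re-smoothed to ultrametric before use. Because the same underlying
  draws are scaled across k at a fixed seed, variance levels are matched
  replicates.

What the generator does **not** emulate: topological estimation error in
the constituent trees (restrictions are topologically correct; only ages
are perturbed), autocorrelated rate structure, calibration-induced bias
shared across nodes, and taxon-name inconsistencies between studies.
Passing tests therefore show robustness of the assembly to sparsity and
age noise, not to constituent-topology error — the empirical behaviour on
real collections additionally depends on the latter.

## Problem sizes and determinism

The validation suite uses 100 random models of 10–40 leaves for the
exact-recovery property, three 51-leaf collections (seeds 1–3) per noise
level for the accuracy and time-recovery checks, 50 random instances per
oracle-equivalence check, and 1000 Monte-Carlo replicates for the
noise-variance calibration. All randomness flows from explicit integer
seeds (`numpy` Generators and seeded `random.Random` for the tree
simulator); identical seeds give byte-identical outputs end to end.

## Known limitations

- Node-age uncertainty is not propagated; the supertree carries point ages.
- Collections whose co-occurrence graph is disconnected are rejected rather
  than assembled piecewise; the supported remedy is grafting user-specified
  outgroup anchors (label and age) onto every input.
- Strong topological conflict between inputs can make the consensus matrix
  non-ultrametric beyond what smoothing can reconcile gracefully; the
  algorithm still terminates, but no optimality statement attaches to the
  result in that regime.
- Taxon matching is exact string equality after whitespace normalisation;
  synonym resolution is out of scope.
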