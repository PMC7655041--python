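# Methods

## Connectome representation

A structural connectome is a dense symmetric nonnegative `N x N` matrix with
zero diagonal; entries are streamline-count surrogates. Matrices are
validated at load (symmetry within 1e-10 relative tolerance, nonnegativity,
no NaN); asymmetric input is rejected rather than silently symmetrized.
Region centroids are in mm; indices are 0-based internally.

Three weight conventions are derived from the raw weighted matrix: binary
(the 0/1 support indicator), weighted (the counts themselves), and distance
(`1/D` on the support, `D` the Euclidean centroid distance matrix). The
corresponding length matrices place `inf` off the support so that path-based
measures cannot leave the connectome. The weighted lengths use the monotone
remap `L = -log10(W / (max W + 1))`; the unit added to the denominator keeps
the strongest connection at a strictly positive length. Density thresholding
keeps the `k = round(d * N(N-1)/2)` strongest undirected edges (round half
up); ties at the cutoff break in lexicographic `(i, j)` order so results are
platform-independent. Group-level connectomes average the raw weighted
matrices entrywise and are then thresholded at the same density as
individual connectomes — the group matrix receives exactly the per-subject
treatment; nothing in the pipeline motivates a different group density.

## Communication measures

* **Shortest path efficiency.** Dijkstra on the length matrix;
  `SPE = 1/Λ*`, unreachable pairs 0. Predecessors are recomputed from the
  distance matrix with lexicographic tie-breaking (`pred(i,j)` is the
  smallest `u` with `Λ*(i,u) + L(u,j) = Λ*(i,j)`), so the path reconstructed
  for search information is deterministic even when shortest paths are
  degenerate. Equality uses relative tolerance 1e-9.
* **Navigation.** The next hop from `u` toward target `j` is the neighbor of
  `u` minimizing `D(·, j)`, ties to the lower region index; it depends only
  on `(u, j)`, so failures are exactly cycles. A navigation fails when a
  node is revisited, the current node has no neighbors, or the hop count
  exceeds `N` (a guard against floating-point tie pathologies; the revisit
  rule alone already bounds paths). Failed entries carry efficiency 0 —
  consistent with "efficiency" semantics — and propagate as ordinary feature
  values downstream.
* **Diffusion.** `T` row-normalizes `W`; mean first passage times come from
  the fundamental matrix `Z = (I - T + 1 pi^T)^{-1}`,
  `H(i,j) = (Z(j,j) - Z(i,j)) / pi(j)`, solved as a linear system rather
  than by simulation or explicit inversion. The chain must be irreducible:
  fragmented graphs are rejected with the component count named.
* **Search information.** `SI(i,j) = log2 P(Ω(i,j))` with transition
  probabilities always built from the weighted matrix, whatever length
  scheme selected the path. The value is nonpositive as defined (larger =
  the efficient route is more accessible); a `negate` option exposes the
  conventional sign-flipped form, off by default. Pairs without a path are
  NaN and are excluded pairwise from correlations; in feature matrices they
  are imputed with the column minimum (preserving "less accessible"), while
  efficiency-type masked entries impute as 0.
* **Communicability.** Matrix exponential (`scipy.linalg.expm`) of the raw
  binary adjacency, or of the strength-normalized matrix
  `W' = W / sqrt(s s^T)` for weighted/distance schemes. The square-root
  normalization follows the standard strength correction for weighted
  communicability; isolated nodes make it undefined and are rejected.

Asymmetric measures (NE, DE, SI) are symmetrized as the arithmetic mean of
the two directions. The full battery is 15 matrices (5 models x 3 schemes),
plus the thresholded SC and the Euclidean distance matrix as benchmarks: 17
predictors for coupling, and 15 + SC + FC for behavior prediction.

## Synthetic study conditions

The generator emulates the statistical features the analyses rely on, not
brain anatomy:

* **Geometry.** `N` centroids uniform in two mirrored half-ellipsoids
  (semi-axes 28 x 60 x 45 mm, hemispheres separated across the midline), so
  navigation and hemispheric stratification are meaningfully exercised.
* **Template connectome.** Edge probability proportional to
  `exp(-D / decay_mm)` (default decay 30 mm), iteratively calibrated so the
  expected density matches the target (default 0.25 before thresholding);
  integer weights `max(1, round(LogNormal))` with log-mean decreasing in
  distance (scale `log 20`, sd 0.8), giving heavy-tailed weights
  anticorrelated with distance. A random spanning tree across fragments
  guarantees connectivity.
* **Subjects.** Multiplicative lognormal edge noise (default sd 0.2 on the
  log scale, half of the variance shared within family) around the shared
  template; family sizes drawn from {1: 0.5, 2: 0.3, 3: 0.2}; ages uniform
  22-35, sexes balanced. Optional degree-preserving rewiring of a fraction
  of edges adds topological individuality.
* **FC.** Upper triangle `rho * z(C_gen) - gamma * z(D) + sqrt(1 - rho^2 -
  gamma^2) * eps`, `z` the rank-based inverse-normal standardization,
  squashed through tanh into (-1, 1), unit diagonal. `rho` controls the
  Spearman coupling to the generating communication matrix (recovery
  experiments use rho = 0.6, gamma = 0.2).
* **Behavior.** `y = Z_S beta + age b_a + sex b_s + eps` where `Z_S` are the
  planted feature columns after the same rank-based inverse-normal transform
  the preprocessing applies — effects are then comparable across
  heavy-tailed edge weights and survive the downstream rank normalization.
  Default betas are one-signed (`0.5 + |N(0,1)|`), a coherent component of
  the kind NBS-style selection assumes. Noise is scaled so the feature term
  explains `target_r2` of the feature-plus-noise variance (default 0.3).
  Planted supports are connected edge sets grown on the complete region
  graph: communication matrices are defined for polysynaptic pairs, and
  planting the signal there is precisely what separates communication
  features from the sparse SC matrix.
* **Null connectomes.** Maslov-Sneppen double-edge swaps with weights
  attached to edges: degree sequence and edge-weight multiset preserved
  exactly, disconnecting swaps rejected.

What the generator does **not** emulate: hemodynamics or any biophysical
forward model for FC, tractography biases, realistic weight-degree
correlations, negative FC structure beyond the tanh squash, and behavioral
batteries with item-level structure. Passing recovery suites therefore shows
the pipeline recovers planted effects under its own generative assumptions,
not that those effects exist in real data.

## Behavior prediction

Scores are normalized by the van der Waerden transform
`Phi^{-1}(rank / (n+1))` and residualized on age and sex by OLS. Folds
assign whole families greedily to the smallest fold, shuffled per
repetition; lasso and NBS consume the same fold plan.

Lasso: columns standardized on training data; a decreasing log-spaced path
of 100 penalties from `lambda_max` (smallest all-zero penalty) to
`0.01 lambda_max`; the inner family-aware tenfold CV selects the penalty
with the highest mean out-of-fold Pearson r — matching the accuracy measure
reported outside — with ties going to the sparser model; refit on the full
outer training set (coefficients returned on the original scale).

NBS: edgewise Pearson correlations converted to
`t = r sqrt(n-2) / sqrt(1-r^2)`; suprathreshold edges (`t > 3` and
`t < -3` separately) grouped into connected components on the region graph;
component size is edge count (extent). The familywise p-value is the
fraction of label permutations (default 1000) whose largest same-sign
component is at least as large. The per-subject mean weight of each retained
component enters an OLS model (at most bivariate). A component is used only
if it exists; by default it must also reach permutation p < 0.05
(configurable), matching standard NBS usage. Folds with no admissible
component score exactly 0. Selection is deterministic given the threshold —
only p-values are stochastic.

## Coupling and ranking

Coupling is Spearman's rho (midranks for ties) over upper-triangle entries,
computed per subject and for group-averaged SC/FC; strata restrict to
SC-connected, SC-unconnected, or intrahemispheric pairs. FC matrices are
never thresholded. The Euclidean-distance benchmark is correlated with its
sign flipped (shorter distance, stronger FC) and reported signed.

Rankings use distribution medians (rank 1 best, average ranks on ties).
Pairwise comparisons are repeated-measures t tests with paired Cohen's d
(mean of differences over the sd of differences) and Bonferroni correction
at `alpha / C(m, 2)` — 136 comparisons for the 17-predictor family, 21 for
the model-grouped 7, 3 for the scheme-grouped 3. The behavioral paired unit
is the per-repetition mean accuracy (10 values for 10 repetitions). The
repeated-measures ANOVA uses the standard one-way within-subject
decomposition with `df = (k-1), (k-1)(n-1)`; for 17 predictors and 5
dimensions this gives (4, 64) error degrees of freedom. The combined ranking
is a weighted average of rank sets over the 15 models + SC (FC excluded):
equal weights for one behavioral and one functional set, 0.25/0.25/0.5 when
both lasso and NBS behavioral rankings are supplied.

## Problem sizes and numerical notes

The recovery suites run at the sizes the package documents as its reference
conditions: N = 68 regions for coupling recovery (7-20 subjects per seed,
20 seeds), n = 200 subjects for behavioral planting, N = 20-36 regions for
NBS recovery and the randomized-connectome comparison. With ten
near-independent planted edges the largest attainable per-edge correlation
is `1/sqrt(10) ~ 0.32`; the NBS recovery experiments therefore plant
`target_r2 = 0.85` with unit betas, putting the expected edgewise t near
4.4 against the threshold of 3, and recovery is summarized as the median
Jaccard over three independent plantings (a single draw can push one edge
below threshold through chance intercorrelation).

Monte-Carlo oracles in the test suite use 2 x 10^5 walkers for hitting
times and 10^6 walkers for path probabilities, compared at three standard
errors. Shortest-path and navigation implementations are checked against
exhaustive path enumeration and an independently written greedy simulator
on 50 random small graphs each.

Known limitations: navigation tie-breaking by region index is one of
several defensible conventions; the N-hop cap is a safety net that should
never bind on generic geometry. Degenerate shortest paths make search
information convention-dependent — the lexicographic predecessor rule picks
one path deterministically. The pipeline assumes nonnegative weights and
undirected connectomes throughout; directed (send/receive asymmetric)
analyses are out of scope.
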