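# Methods

`docnet` implements a weighted functional-connectome analysis for
disorders of consciousness (DoC): from per-subject ROI time series it
builds Fisher-z functional networks, characterises them with ten weighted
graph measures integrated over a sparsity sweep, tests group differences
nonparametrically, and classifies minimally conscious state (MCS) against
vegetative state (VS) patients. This note records the models, the choices
made where the design was genuinely open, and what the synthetic cohorts
do and do not establish.

## Network construction

For each subject with 90 regional time courses, connectivity is the
Pearson correlation matrix, Fisher r-to-z transformed
(`z = atanh(r)`, with r clipped to ±(1 − 1e−7) so numerically perfect
correlations stay finite) and the diagonal forced to zero. Negative
entries are set to zero: negative couplings are conventionally excluded
from weighted functional connectomes, and no negative-edge model is
offered.

Sparsity `s` is the retained-edge count over the `N(N−1)/2` possible
undirected pairs. At each of the 36 levels `s = 0.05, 0.06, …, 0.40` the
`k = round(s·N(N−1)/2)` strongest edges are kept with their z weights.
Two conventions are ours, declared for reproducibility because the edge
count is otherwise ambiguous: `k` rounds half away from zero, and ties at
the cut break by smallest (row, column) index. Both make the sweep
deterministic, and the edge sets are nested across the sweep by
construction. If fewer than `k` strictly positive edges exist the sweep
saturates, keeps all positive edges, and logs a warning.

## Graph measures

All ten measures are weighted. An edge of weight `w > 0` has length
`1/w` — the standard connectome convention; distances `d_ij` are weighted
shortest-path lengths. Unreachable pairs contribute zero to efficiencies
and are excluded from the characteristic path length, which keeps both
finite at low sparsity.

* nodal efficiency `E_i = (1/(N−1)) Σ_{j≠i} 1/d_ij`; global efficiency is
  its node mean.
* characteristic path length: mean `d_ij` over reachable ordered pairs.
* nodal clustering: Onnela geometric-mean form,
  `C_i = (1/(k_i(k_i−1))) Σ_{j≠h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}` with
  `ŵ = W/max(W)` and binary degree `k_i`; zero when `k_i < 2`. The
  measure is named but not formalised in the source literature; Onnela's
  form is the common choice in connectomics toolboxes.
* nodal local efficiency: global efficiency of the subgraph induced by a
  node's neighbours (original weights, the node itself removed); zero when
  `k_i < 2`. Clustering coefficient and local efficiency are node means.
* degree centrality: node strength `Σ_j w_ij`.
* betweenness centrality: weighted shortest-path betweenness (Brandes,
  multiplicity counted), normalised by `(N−1)(N−2)/2`. Group comparisons
  are invariant to this constant. Hop-count betweenness is not offered;
  weighted paths keep the measure consistent with the others.
* eigenvector centrality: the nonnegative unit-norm leading eigenvector of
  `W` restricted to the largest connected component; zero outside it.
  Computed by power iteration with a diagonal shift equal to the maximum
  strength (the shift leaves the eigenvector unchanged but keeps the
  dominant eigenvalue simple, so bipartite-like components still
  converge); relative tolerance 1e−13 on the iterate difference.

Each measure's profile over the sweep is summarised by its trapezoidal
integral (AUC), one threshold-free scalar per subject × measure × scope —
4 global and 6×90 nodal values, 544 in all.

All ten measures are verified against independent brute-force oracles
(Floyd–Warshall distances, exhaustive simple-path enumeration, explicit
triple loops, dense eigendecomposition) to 1e−9 on seeded random graphs
of up to 8 nodes.

## Group comparison

The statistic is the difference of group means of a measure's AUC. Labels
are reshuffled uniformly (10,000 permutations by default; an exhaustive
mode enumerates all label splits for small groups) and the two-tailed
p-value uses the add-one estimator `(b+1)/(m+1)` with ties counted, so p
is never zero and exactly reproduces the exhaustive distribution when all
splits are enumerated. No multiple-comparison correction is applied by
default, mirroring uncorrected per-node reporting at α = 0.05; Bonferroni
and Benjamini–Hochberg options exist. Type-I error is calibrated: under a
null simulation the rejection rate at α = 0.05 stays within [0.04, 0.06].

Connectivity itself is summarised per group by the entrywise mean of the
subject z matrices (before rectification) and the moments/histogram of
its upper triangle.

## Classification

MCS is the positive class, VS the negative. Features are the 544 AUCs in
a fixed order (4 global, then each nodal measure across regions in atlas
order). The pipeline per evaluation:

1. standardise features;
2. embedded L1 selection: minimise logistic cross-entropy plus
   `λ‖ω‖₁`, `C = 1/λ`; the surviving nonzero coefficients are the
   features (liblinear coordinate solver, tolerance 1e−8, deterministic);
3. SMOTE the minority class up to balance: each synthetic sample is
   `x_i + δ(x̂_i − x_i)` with `x̂_i` one of the k = 5 Euclidean nearest
   minority neighbours and `δ ~ U(0,1)`; parents are recorded so every
   synthetic point is verifiable as a convex combination;
4. linear-kernel SVM (cost 1; RBF available), evaluated by leave-one-out
   cross-validation; pooled confusion counts give accuracy, sensitivity
   and specificity in percent.

Two leakage policies are provided. The default fits standardisation,
selection and SMOTE inside each training fold, so nothing from the
held-out subject reaches the model. `paper_mode` performs them once on
the whole cohort before cross-validation — a reading of "after feature
selection and oversampling" that is common in the applied literature but
optimistically biases estimates; synthetic samples there only ever train,
so the confusion denominators remain the real class counts. The SMOTE
neighbourhood size and the SVM kernel/cost are unreported in comparable
studies; k = 5 and a linear kernel with cost 1 are the package defaults.
If a fold selects no features, the fold predicts the majority class and
logs a warning. A sweep over `C = 0.10 … 1.00` step 0.01 (91 settings)
reports per-C performance and flags the best accuracy.

## Synthetic cohorts

The generator emulates the statistical structure of a three-group DoC
study — healthy controls (NC, n = 30), MCS (n = 19) and VS (n = 40) — with
90 regions and 200 usable volumes at TR = 2 s. Targets: group-averaged
upper-triangle Fisher-z mean/SD of 0.31/0.18 (NC), 0.22/0.14 (MCS),
0.21/0.14 (VS).

Construction, per group:

* a 4-module block z-matrix (within/between-module separation carrying
  half the target variance, i.i.d. symmetric Gaussian edge noise the other
  half) with the target mean imposed exactly;
* calibration by alternating projection: positive-definitization
  (eigenvalue clipping at 1e−6, diagonal renormalised to 1) alternated
  with an affine restoration of the target z moments, iterated to
  tolerance 1e−4. Plain one-shot projection is not enough — on a 90×90
  matrix it shrinks the z mean by roughly 0.07 at the NC target — while
  the alternation converges to a positive-definite correlation matrix
  with the exact moments;
* regional effects: each (region set, factor) entry multiplies z
  rows/columns of its regions, followed by one final projection. Defaults
  give patients a mild frontoparietal reduction (factor 0.90 MCS / 0.85
  VS over 12 regions) and a caudate/thalamus-like elevation (1.15 over 4
  regions); controls carry none. The induced mean shift (≲0.008) is part
  of the group's measured mean;
* subjects: Wishart draws centred on the group covariance, renormalised
  to correlation — positive definite by construction with no projection
  bias. Degrees of freedom ν = 1/sd² + 3 map the requested between-subject
  z jitter (default SD 0.06, a modelling choice: between-subject variance
  is not reported for comparable cohorts) through the Fisher-z variance
  relation;
* time series: Cholesky-factored stationary Gaussian draws, band-limited
  by a temporal Gaussian kernel (SD 1 TR). The same filter acts on every
  region, so zero-lag correlations are preserved in expectation while
  spectra acquire the slow-band character of filtered BOLD.

With default seeds the measured group-averaged z means land within about
±0.01 of the targets; the acceptance tolerance is ±0.02, dominated by
between-subject mean variability (SD ≈ 0.045 per subject, /√n per group).

What the generator does *not* model: hemodynamics, head motion,
physiological noise, spatial structure of the atlas (region sets are
index sets on a synthetic parcellation), volumetric images, or
heavy-tailed/nonstationary signal features. Passing tests therefore
establish that the pipeline recovers the structure it assumes — correct
formulas, calibrated inference, detectable imposed effects — not that it
would attain any particular performance on real patient data. In
particular, reported MCS/VS accuracies from real cohorts are covered only
at the formula level (the confusion-matrix arithmetic), since those data
are not available.

## Problem sizes and determinism

Default analyses run on the full 89-subject, 90-region, 36-sparsity
design; tests exercise the same code on reduced designs (e.g. 20 regions,
16–20 subjects, coarser C grids) chosen to keep the suite fast while
covering every stage at full feature dimensionality where the contract
demands it (feature length 544 is always checked at 90 regions). One
global seed fans out to per-stage and per-subject child generators
(`SeedSequence` spawning), so identical configurations reproduce every
table byte-for-byte and disabling one stage does not shift another's
stream.

## Known limitations

* The sparsity denominator counts all possible pairs; subjects with very
  few positive correlations can saturate the sweep (logged, not fatal).
* Characteristic path length silently conditions on reachability; at
  sparsities low enough to fragment the network it measures the connected
  part only.
* The exhaustive permutation mode enumerates `C(n, n_a)` splits and is
  only practical for small groups.
* `paper_mode` estimates are optimistically biased by design; use them
  only to compare against whole-cohort-selection literature.
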