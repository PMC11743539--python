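# Methods

This note documents the statistical model the package implements, the
numerical conventions it fixes, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the underlying
analysis recipe was open.

## Pipeline

1. **Connectivity.** Pearson correlation between every pair of regional
   mean time series, Fisher-transformed (z = arctanh r) with the diagonal
   set to zero.  Correlations numerically at ±1 off-diagonal are an error,
   not clipped: they indicate duplicated regions, and clipping would
   silently distort every downstream metric.  An outlier screen flags (but
   never drops) subjects whose mean off-diagonal z lies more than 3 SD
   from the cohort mean, both computed leaving the subject out — the
   include-self variant cannot flag gross outliers at small n because the
   outlier inflates the reference SD (the deviation is capped at
   (n−1)/√n SDs).  Pooled skew/kurtosis of z values are reported
   descriptively; nothing gates on normality.
2. **Thresholding.** Proportional thresholding keeps exactly
   k = round(s·N(N−1)/2) strongest pairs (round half away from zero), for
   s from 10% to 50% in 1% steps (41 graphs).  Default ranking is by
   signed z — "strongest connections" read as strongest positive
   coupling — with an absolute-value mode available by configuration.
   Exact ties at the cutoff are broken toward the lexicographically
   smaller (i, j) pair so that thresholding is a pure function; ties are
   measure-zero for real data but must not be implementation-defined.
   Connectedness is not enforced at low sparsity; disconnection is
   handled by the metric conventions below.
3. **Metrics.** Degree, clustering, characteristic/nodal path length,
   global/local/nodal efficiency, betweenness (Brandes, unnormalized; a
   normalization flag exists).  Conventions for degenerate cases: nodes
   with degree < 2 have clustering and local efficiency 0 and are included
   in network means (the defining sums divide by N); path-type averages
   run over reachable pairs only, isolated nodes are NaN; efficiencies use
   1/∞ = 0.  Metric curves across the sweep are summarized by trapezoidal
   AUC on the exact sparsity grid, NaN points dropped pairwise; AUC, not
   any single-threshold value, is what group statistics consume.
4. **Small-world propensity.** Per node,
   γ_i = (C_obs/C_null) × (L_obs/L_null), with null values being ensemble
   means over random networks with the same node and edge counts.  The
   multiplicative form is implemented exactly as defined even though, as a
   product, longer-than-random paths *increase* γ_i; because that behavior
   is surprising relative to classical small-worldness, the classical
   ratio σ_i = (C_obs/C_null)/(L_obs/L_null) is always emitted alongside,
   clearly labeled, and no intent is guessed.  The default null is
   degree-preserving Maslov–Sneppen rewiring (10·m attempted double-edge
   swaps per realization, proposals creating self-loops or multi-edges
   rejected; an unswappable graph such as a star falls back to the source
   graph with a warning), the field standard because it does not inflate
   clustering ratios through degree mismatch; an Erdős–Rényi G(n, m) null
   is available to match the literal "same number of nodes and edges"
   reading.  100 realizations by default, balancing ~10% Monte-Carlo error
   on null means against runtime.
5. **Inference.**  Edgewise OLS of Fisher-z on
   [intercept, group, age, mean FD]; the group-coefficient t with no
   covariates reduces exactly to the pooled two-sample t.  Permutations
   follow Freedman–Lane (shuffle reduced-model residuals, add back the
   nuisance fit), preserving nuisance structure; one shuffle log is reused
   across all edges, preserving the joint null dependence.  Permutation
   p-values use (1 + count)/(1 + n_perm), which cannot be zero.  Edgewise
   p-values get Benjamini–Hochberg FDR; NBS decomposes suprathreshold
   edges (|t| above the two-sided parametric critical value at the primary
   p, default 0.001, always logged in the manifest since results depend on
   it) into connected components whose edge counts are referred to the
   permutation distribution of the maximum count; AUC group tests are
   Welch t by default (a pooled option exists) with permutation p and BH
   across the (metric, node) family, zero-variance features excluded with
   a count.  Edgewise-FDR and NBS results are emitted side by side, never
   mixed in one table.  Effect summaries include the group mean difference
   and the point-biserial correlation.

Determinism: one master seed; each stage derives an independent generator
from (seed, stage name), so any stage re-run in isolation reproduces the
full run's numbers, and the manifest checksums every output table.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
fMRI physics: zero-mean Gaussian innovations with a community-structured
correlation matrix (4 equal blocks, within-block r = 0.4, between-block
r = 0.1 — a regime whose thresholded graphs are small-world-like), colored
by an AR(1) with coefficient 0.3 and scaled so stationary marginal
variances are exactly 1, which makes covariance-scale and
correlation-scale effects coincide and gives every region lag-1
autocorrelation equal to the AR coefficient.  Group differences are
planted by adding a delta to chosen entries of the treatment group's
correlation matrix; positive-definiteness of the perturbed matrix is
verified at construction and violations are an error.  Default design
mirrors the emulated study: arms of 67 and 72 subjects, 116 regions, 240
time points; ages Normal(22.09, 2.44) / Normal(21.69, 2.57) years and mean
framewise displacement half-normal with scale 0.15 mm in both arms
(matched nuisance distributions).  No effect-size estimate on the raw
correlation scale is available from the emulated study, so the default
effect_delta is 0 (pure null); validation studies plant 0.3, a moderate,
clearly recoverable shift at n = 40 per arm.

Not emulated: hemodynamics, physiological noise, scanner drift, motion
artifacts, spatial autocorrelation of parcels, and non-Gaussian tails.
Passing tests therefore demonstrate that the *statistical machinery* is
correct and calibrated for data satisfying its assumptions — not that
those assumptions hold for any particular scanner or population.

## Validation studies and their problem sizes

`fctopo.validation` measures operating characteristics by simulation; the
test suite and `scripts/acceptance.py` run them at sizes chosen to keep
the whole suite in minutes on one CPU while leaving Monte-Carlo error well
inside the asserted bands:

- **Null calibration** (20 vs 20 subjects, 20 regions, 240 time points,
  200 permutations): the edgewise rejection rate at α = 0.05 sits at the
  permutation-test point mass 10/201 ≈ 0.0498.  The NBS family-wise error
  is 0.037 (measured with 1,000 replicates): extent-based NBS is
  *conservative* here because the maximum-component-size statistic is
  integer-valued and heavily tied, and ties count as "at least as
  extreme".  This is a known property of extent-based cluster statistics
  at small graph sizes, not an implementation defect; the calibration
  study uses a liberal primary threshold (0.1) because at stringent
  thresholds the null max is almost always zero and the check would be
  uninformative.
- **Edgewise-FDR recovery** (three disjoint between-block edges, delta
  0.3, 40 vs 40, 500 time points): sensitivity ≈ 1.  Note a structural
  constraint: BH over E edges can only reject k edges if the permutation
  p floor 1/(1+n_perm) ≤ k·q/E; with E = 190, k = 3, q = 0.05 this
  requires n_perm ≥ 1267, so these studies use 2,000 permutations.  At
  1,000 permutations the floor (≈0.001) exceeds the BH threshold
  (≈0.00079) and *no* small rejection set is attainable regardless of
  effect size — a caveat that applies equally to edgewise permutation-FDR
  analyses on full connectomes.
- **NBS recovery** (connected 5-edge between-block path, delta 0.3, same
  design, primary p = 0.001, 200 permutations): the planted component is
  recovered with FWE p ≤ 0.05 in ≈100% of replicates.  The path shape
  keeps the perturbed correlation matrix positive-definite (a 5-edge star
  at delta 0.3 would not be).

## Known limitations

- Binary undirected graphs only; no weighted or directed variants, no
  dynamic (windowed) connectivity, no partial correlation.
- The γ_i index is reported as defined (multiplicative); users comparing
  against classical small-world literature should use the σ_i column.
- Degree-preserving rewiring mixes poorly on graphs with very constrained
  degree sequences; the swap-acceptance fallback is reported by warning.
- Group labels enter inference as a two-level factor; designs with more
  arms or continuous treatments are out of scope.
- The sample-accounting record carries two conflicting printed recruitment
  figures (142 and 139) from the emulated study verbatim; the analyzed
  count is recruited − excluded = 139.
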