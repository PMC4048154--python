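# Methods

## The problem

A whole-brain functional connectome over N grey-matter voxels has
N(N−1)/2 distinct connections — hundreds of millions at typical
resolutions.  Testing every connection for a difference between two
conditions and correcting family-wise across all of them (e.g. with a
max-t permutation test) is valid but badly underpowered, because no single
connection is likely to survive a correction over ~10⁸ tests.  `connclust`
implements two cluster-level statistics that recover power by exploiting
the spatial smoothness of BOLD fMRI: connectivity changes are aggregated
per voxel and inference is carried out on spatially contiguous clusters of
changed voxels rather than on individual connections.

## The statistics

For a repeated-measures design with n subjects scanned under conditions A
and B:

1. Per scan, the N×T voxel timecourses give an N×N Pearson correlation
   matrix.
2. For every matrix element, a paired t-statistic is computed across
   subjects on the per-subject differences d_i = A_i − B_i
   (dof = n − 1).
3. A cluster-forming threshold t0 > 0 binarizes the t-matrix: element
   (u, v) is a *cluster link* when t > t0 (increases) or t < −t0
   (decreases).  Both signs are analysed when both directions are of
   interest.
4. Row sums of the binary matrix give each voxel's link count; mapped back
   into image space this is a univariate map of how many connections each
   voxel has changed with the rest of the brain.
5. Connected components of the voxels with at least one link are extracted
   under face-or-edge adjacency (18-connectivity in 3-D, 8-connectivity in
   2-D).
6. Each component yields two statistics: **CSS** (cluster size statistic),
   its voxel extent, and **CMS** (cluster mass statistic), the total link
   count over its member voxels.

Because the row-sum computation is taken as the definition of CMS, a link
whose two endpoints fall inside the same cluster contributes **2** to the
cluster's mass.  The narrative definition ("links between the cluster and
the rest of the brain") could be read as counting each link once; both
semantics are implemented (`mass_mode="endpoint"` is the default,
`mass_mode="link"` counts each link once) because which one the original
description intended for intra-cluster links is ambiguous.

## Inference

Significance is assessed by sign-flip permutation.  Under the null
hypothesis, each subject's difference d_i is symmetric around zero, so all
2ⁿ relabellings f ∈ {±1}ⁿ are equally likely.  For every relabelling the
entire workflow (t-matrix → threshold → link counts → clusters) is
recomputed and the *maximum* CSS (and CMS) anywhere in the image is
recorded.  A cluster in the observed labelling is significant at
FWE-corrected level p when it exceeds the 100(1−p)th percentile of this
maximum distribution (one-sided), or the 100(1−p/2)th percentile for
two-sided reporting; the reported two-sided p doubles the one-sided count
p, capped at 1.  Conventions, all deliberate and conservative:

- the identity labelling is always a member of the permutation set, so no
  reported p can fall below 1/P;
- ties count as extreme (count of maxima ≥ observed, divided by P);
- thresholding uses strict inequality (t = t0 forms no link) so behaviour
  at ties is deterministic;
- the maximum-cluster distribution is provably identical for +t0 and −t0
  under a sign-symmetric flip set, so the positive-threshold null serves
  clusters of both signs (a paranoid mode recomputes both and asserts
  equality);
- for n subjects only half of the 2ⁿ flips are informative (f and −f give
  mirrored t-matrices); the engine exploits this only through the algebra
  (sum of squares is flip-invariant), not by halving the set, so the
  identity row stays explicit.

The element-wise max/min-t test — the single-connection baseline — records
the maximum and minimum t over all unique off-diagonal elements per
permutation; an element is two-sided significant at level α when its t is
in the top α/2 tail of the max distribution or the bottom α/2 tail of the
min distribution.

Permutations are processed in blocks: with D the n×M matrix of
upper-triangle differences, sign flips leave Σd² unchanged, so a block of
permuted t-vectors costs one (b×n)(n×M) product and
t = s₁·√((n−1)/(n·Σd² − s₁²)) elementwise.  Zero-variance elements
(denominator ≤ 10⁻¹² of its scale) are forced to t = 0 — they can never
form links — rather than failing the run, so degenerate synthetic inputs
remain usable.

## Threshold selection (isocontour curves)

The cluster-forming threshold t0 trades spatial specificity against
sensitivity.  The isocontour procedure computes, for a grid of t0 values
and a single shared (optionally reduced) permutation set, the *critical
cluster size*: the smallest integer s such that the fraction of permutation
maxima ≥ s is at most α.  Critical size against t0 is fitted with an
interpolating cubic spline; inverting the curve gives the t0 associated
with a desired critical extent.  Because only permutation maxima are used,
the procedure reveals nothing about the significance of the observed
labelling's clusters — there is no double dipping.  Choices made here:

- flips are shared across the threshold grid, removing Monte-Carlo jitter
  between grid points;
- raw critical sizes are made non-increasing by isotonic regression before
  the spline fit (subset-permutation noise can break the monotonicity that
  holds in expectation); raw values are kept alongside;
- inversion evaluates the spline on a dense grid and returns the largest
  t0 still reaching the target size, which is well defined on plateaus; a
  monotone (PCHIP) interpolant is the fallback if the cubic overshoots;
- no extrapolation outside the observed size range;
- the default grid spans t-values whose nominal two-sided p runs from 1e−2
  to 1e−8 at the design's dof.

## Preprocessing (in scope)

- Group mask: mean of per-subject probabilistic grey-matter maps,
  thresholded inclusively (mean ≥ 0.8 by convention; the threshold is a
  parameter).
- Low-pass filter: zero-phase Butterworth (order 4 by default, recorded in
  the run log), cutoff 0.1 Hz — the BOLD band edge.
- Baseline correction: residualization against a discrete cosine (DCT-II)
  basis up to order 2 plus an intercept.  Note a cosine basis does not
  annihilate a linear ramp exactly; it removes the bulk of low-frequency
  drift, which is its purpose.
- Nuisance regression: per-scan covariates (e.g. realignment parameters)
  are demeaned and included in the same regression.
- Zero-variance voxels fail the correlation step by default, with an
  opt-in mode that zeroes the affected correlations instead.
- Correlations are used raw; a Fisher-z option exists but defaults off
  because the t-statistics are defined on connectivity values directly.

Realignment, slice timing, segmentation, normalisation and the spatial
smoothing of *real* data are upstream concerns for standard neuroimaging
tools and are out of scope.

## Synthetic data generator

`SimulationConfig`/`generate_groups` emulate a single-slice study:

- groups A and B: independent unit-variance Gaussian timecourses for each
  of n scans on a masked 2-D grid;
- group C: A plus a zero-phase 0.1 Hz sinusoid of amplitude CN·σ_N
  (σ_N = 1, amplitude set before smoothing) added to a Euclidean disc of
  radius R voxels (the *primary cluster*) and to round(CV·|disc|) voxels
  sampled uniformly outside it, re-drawn per trial.  A shared zero phase is
  what makes the contrast voxels co-fluctuate and hence changes
  connectivity;
- all groups then receive, identically: an order-1 autoregressive filter
  (coefficient 0.3) standing in for the temporal autocorrelation of real
  BOLD data, Gaussian spatial smoothing of 8 mm FWHM on 4 mm voxels, and
  the 0.1 Hz low-pass.

Default conditions are n = 12 scans per group and TR = 2 s, matching a
repeated-measures fMRI study of that size.  The slice is a 20×20
fully-true mask with T = 120 timepoints — a deliberately scaled slice
chosen once so that thousand-fold trial repetition is tractable on a
single CPU; the reference full-scale analysis ran a whole grey-matter
slice with T = 180.  What the generator does *not* emulate: physiological
noise spectra, inter-subject anatomical variability, motion artefacts, and
anatomically shaped masks.  Passing tests therefore demonstrate the
statistical machinery (calibration, symmetry, ordering of method
performance), not field-strength-specific effect sizes on real scans.

## AFROC evaluation

Detection performance uses the AFROC convention, which matches what a
family-wise-controlled test promises:

- TPR (contrast group C vs noise group B): |C∩ĥ|/|C| where C is the
  primary-cluster voxel set and ĥ the union of member voxels of clusters
  (either sign) whose statistic meets the discrimination threshold;
- FPR (noise A vs noise B): 1 if *any* cluster meets the threshold, else 0.

Mean TPR and FPR over trials, swept over the discrimination threshold,
give the curve; performance is summarised by the partial area under the
curve restricted to FPR ≤ 0.05 (higher family-wise false-positive rates
are not of practical interest).  The partial AUC is computed on the
thresholds where the mean FPR changes (intermediate thresholds add only
zero-width segments), anchored at (0,0) and linearly interpolated at the
0.05 boundary; standard errors come from a bootstrap over trials (paired
across methods for the CMS−CSS difference).

One step description in the source material assigns the TPR comparison to
"groups A and B" and the FPR comparison to "B and C"; taken literally the
TPR side would contain no contrast and the FPR side would.  The
surrounding prose (TPR detects the primary cluster; FPR compares two
noise-only datasets) is taken as normative: TPR = C vs B, FPR = A vs B.

## Evaluation conditions frozen in this package

- Null calibration: 20×20 noise-only slices, n = 8 subjects (so the full
  2⁸ = 256 enumeration is exact), cluster-forming threshold t0 = 3 at
  dof 7, α = 0.05, 200 Monte-Carlo replicates; the family-wise rejection
  rate of CSS, CMS and max-t is checked against the binomial 95% interval
  [0.02, 0.09] around 0.05.
- Parameter sweeps: CN ∈ {0.25, 0.4, 0.5}, CV ∈ {1, 2, 3}, R ∈ {1, 2, 3},
  one parameter varied at a time around the base condition (CN = 0.4,
  R = 2, CV = 2, t0 = 5), 300 trials per condition.  Partial AUC is
  expected non-decreasing along each sweep and CMS ≥ CSS, each within one
  (bootstrap) standard error.
- Isocontour round-trip: interpolating a threshold for a target critical
  size and recomputing the critical size at that threshold agrees within
  ±1 voxel.

## Known limitations

- The 2-D cluster adjacency (8-connectivity) includes diagonal neighbours
  and is therefore not the strict planar analogue of face-or-edge-only
  3-D adjacency; it is used because it is the established convention for
  single-slice analyses.
- CMS mass semantics for intra-cluster links are a documented convention,
  not a derivation (see above).
- Critical sizes from reduced permutation subsets are noisy; the isotonic
  adjustment guarantees monotonicity but not unbiasedness at any single
  grid point.
- The whole-brain 3-D problem at full scale (N ≈ 10⁴ voxels, 4096
  permutations) is computationally heavy; the implementation streams
  permutation maxima and never materialises all permuted matrices, but a
  full-scale run is an hours-long batch job, not an interactive call.
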