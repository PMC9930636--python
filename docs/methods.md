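# Methods

This note documents the models, numerical choices and limitations of
`tempostab`, in the spirit of a methods appendix. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Phase-coherence dFC

The instantaneous connectivity of regions *n* and *p* is
`dFC(n,p,t) = cos(θ(n,t) − θ(p,t))`, with phases from the discrete analytic
signal (FFT-based Hilbert transform). Assumptions and choices:

- **Mean removal** is always applied per region before the transform: the
  phase of the analytic signal is only meaningful for a zero-mean
  oscillation. Linear detrending is optional (`detrend=True`).
- **Band-pass filtering is off by default.** The phase-coherence literature
  often filters to a narrow band (e.g. 0.01–0.08 Hz) so the instantaneous
  phase is well defined; a zero-phase second-order Butterworth option
  (`bandpass=(low, high)`) is provided. Defaults favor touching the input
  as little as possible; for broadband empirical BOLD, enabling a band is
  recommended and the choice should be reported.
- **Edge transients.** The discrete analytic signal is distorted within
  roughly 5 samples of either end of the series (observable as spurious
  angles up to ~0.17 rad in an otherwise constant-connectivity signal).
  All timepoints are kept by default; `edge_trim=n` drops *n* samples from
  each end for sensitivity analyses, and the degenerate-limit test uses
  `edge_trim=5`.
- Identity used throughout: each slice equals `c cᵀ + s sᵀ`, hence has rank
  ≤ 2 with nonnegative spectrum. This is why three principal components
  capture 100% of each slice's variance up to floating point, a strictly
  stronger statement than the ≥ 99% one would verify empirically.

The sliding-window alternative (`sliding_window_dfc`) tiles the series into
nonoverlapping windows and computes Gaussian-weighted Pearson correlations.
The taper's σ = L/4, centered in the window and truncated to it; this is a
convention (only "Gaussian window" is standard usage) and is configurable.

## Dominant subspaces

Each slice is eigendecomposed (`scipy.linalg.eigh`, spectrum sorted
descending) and the k = 3 leading eigenvectors retained. Choices:

- **Scaling**: by default column *i* is scaled by √|λᵢ| so
  `D_t D_tᵀ` equals the best rank-k reconstruction of the slice. The
  subspace span — all the principal-angle machinery uses — is unaffected;
  `scaling="unit"` keeps unit-norm eigenvectors for the Mahalanobis rows.
- **Sign convention**: each eigenvector is flipped so its largest-magnitude
  entry is positive. Signs are mathematically indeterminate; a fixed
  convention makes row-pair Mahalanobis distances reproducible across runs
  and platforms. Principal angles are sign-invariant regardless.
- **Numerically null directions**: for rank-2 input the third eigenvalue is
  ~10⁻¹⁶ of the first, and its eigenvector is an *arbitrary* null-space
  direction. Columns with |λ| < 10⁻¹² |λ₁| are flagged
  (`DominantSubspace.null_columns`). The principal-angle computation
  excludes flagged columns and truncates singular directions below 10⁻⁶ of
  the leading one when orthonormalizing; without this exclusion the largest
  principal angle between any two rank-deficient subspaces is randomized
  toward π/2 by the arbitrary third directions. The Mahalanobis covariance
  handles the same degeneracy by ridge regularization (below).

## Stability matrices

**Principal angle.** Both component matrices are orthonormalized
(rank-revealing SVD) and the angles are the arccosines of the singular
values of the cross-Gram matrix `Q_aᵀ Q_b`. "The" angle reported in the
stability matrix is the **largest** principal angle — the member of the
canonical angle set that attains the (0, π/2] range and the convention of
common numerical environments. `which="smallest"|"all"` exposes the rest.
Angles of near-identical subspaces are resolved only to ~√ε ≈ 10⁻⁸ rad
(arccos near 1); tests use tolerances of 10⁻⁷ accordingly.

**Mahalanobis.** The N rows of `D_t` (one k-vector per region) are treated
as a point cloud. The covariance C is estimated from the mean-centered rows
of the *first* argument and regularized as `C + ε·tr(C)/k·I` with
ε = 10⁻⁸ (configurable). Regularization is mandatory, not cosmetic: with
rank-2 slices the third component direction carries no variance and C is
singular by construction. Two modes:

- `rowpair` (default): distance between matched rows of the two subspaces —
  the literal row-difference quadratic form;
- `distribution`: distance of each row of the second subspace from the row
  distribution (mean, covariance) of the first — the point-to-distribution
  reading. It is invariant under a common invertible linear map of both row
  clouds (up to the regularization, which breaks exact invariance at
  ~ε·cond(C)²).

The raw quantity is asymmetric (C comes from one side), so the matrix entry
is symmetrized as `(M(a,b) + M(b,a))/2` and the diagonal set to zero in
rowpair mode. Which semantics published stability matrices of this kind use
is generally ambiguous; both are first-class here and tested.

## Entropy and Frobenius summaries

Entropy follows the image-histogram convention: map entries to [0, 1], bin
into 256 equal-width bins, `E = −Σ p log₂ p` (bits, so E ≤ 8). Angle
matrices map by the fixed theoretical range π/2 — making entropies
comparable across subjects and conditions; Mahalanobis matrices have no
finite bound and use per-matrix min–max (policy selectable). A constant
matrix under min–max yields a single-bin histogram, E = 0, with a warning.
The full matrix including the diagonal is histogrammed.

Frobenius distance between stability matrices of unequal size (e.g. a
261-point rest run vs a 193-point movie run) truncates both to the leading
common T×T block — the minimal, explicit reconciliation; the truncation
size is recorded on the result.

## AR characterization

The lag-1 superdiagonal of a stability matrix — the distance between
successive dominant subspaces — is the stability time course; the lag is
configurable. AR(ρ) models are fitted by conditional least squares with an
intercept. For order selection all candidates ρ = 0…max_order are fitted on
the **common sample** that conditions out the first max_order points, so
their AIC values are comparable; the Gaussian log-likelihood uses the
residual mean squared error, and `AIC(ρ) = −2L + 2ρ`. The selected order is
the **first local minimum** of the AIC curve (ρ = 0 qualifies when
AIC(0) ≤ AIC(1)); a curve with no local minimum falls back to the global
minimum and is flagged. max_order is capped at a third of the series length
to avoid degenerate fits.

A consequence worth knowing: for true white noise the probability that an
AIC rule with its fixed penalty of 2 per order retains ρ = 0 is
asymptotically P(χ²₁ ≤ 2) ≈ 0.84 — AIC is not consistent at the null. A
selection rate much above ~84% on white noise would require a stiffer
penalty (e.g. BIC), which is a different criterion.

## Synthetic generator

`generate_regime_bold` emulates exactly the features the pipeline measures
and nothing else: hidden regimes (partitions of regions into phase-locked
communities with fixed offsets), a shared sinusoidal carrier so relative
phases are precisely the planted offsets and regime switches never reset
the oscillation, and additive white Gaussian noise. Defaults mirror a
typical lifespan fMRI protocol and were fixed as the package's study
conditions: 116 regions; 261 timepoints (rest/sensorimotor) or 193 (movie);
TR = 2 s; oscillation 0.05 Hz (mid BOLD band); noise SD 0.3 of unit
amplitude; 3 regimes over 4 communities; mean dwell 10 samples (20 s) at
rest, with task-like conditions dwelling 4× longer. Dwells are geometric
(memoryless) by default or fixed for exact switch-time ground truth.

What the generator does **not** emulate: hemodynamic convolution, 1/f and
physiological noise, head motion, amplitude differences between regions,
and spatially correlated noise. Passing tests therefore demonstrate that
the machinery recovers planted phase-coupling structure, not that empirical
BOLD satisfies the generator's assumptions.

Observed behavior under these conditions (verified by tests): longer dwell
times concentrate the angle-value histogram and lower entropy, which is the
mechanism behind the task-vs-rest entropy ordering; lag-1 angle spikes
localize regime switches to within ~3 samples (the analytic-signal
transient width).

## Cohort statistics

Ages are binned by integer truncation into {18–20, 21–25, …, 76–80, 81–88}
and grouped young/middle/old at 40/60. Two-sample comparisons are
nonparametric (rank-sum unpaired, signed-rank paired) with Jarque-Bera and
D'Agostino-Pearson normality screening attached to every result; p-values
are reported uncorrected by default (an FDR pass can be applied downstream).
The lifespan trend model is the minimal quadratic
`E ~ β₀ + β₁·(age − mean) + β₂·(age − mean)²`; centering the age term
decorrelates the linear and quadratic columns. `curvature_sign` = sign(β₂)
distinguishes U from inverted-U. Richer term sets (sex, motion, interactions)
are deliberately out of scope.

The bundled AAL-116 network file (`data/aal116_networks.yaml`) is a
reference reconstruction of common DMN/CEN/SM/salience/visual usage, not a
measured atlas mapping; it is plain YAML and meant to be edited.

## Problem sizes

Default test and acceptance runs use the full 116 × 261 shape for
single-subject checks (a fit takes well under a second), 20 subjects × 2
conditions for the cohort-ordering analysis, 50 seeded replicates for AR
order-selection rates, and 1000 replicates for the regression type-I
calibration — sizes chosen so the whole suite completes in a few minutes on
one CPU while keeping Monte-Carlo standard errors a few percent.

## Known limitations

- The largest-principal-angle convention discards the smaller canonical
  angles; two subspace pairs sharing one direction but differing in the
  others are indistinguishable from pairs differing in all directions.
- Row-pair Mahalanobis distances are sensitive to eigenvector ordering
  swaps when λ₁ ≈ λ₂ and to the sign convention under heavy noise; the
  principal-angle metric is immune to both.
- Entropy under per-matrix min–max scaling is not comparable across
  subjects in absolute terms; use the fixed-range policy (angle metric)
  for cross-subject claims.
- The AR likelihood is conditional (not exact ML); for the short series
  typical of fMRI runs the difference is immaterial relative to the
  order-selection variability documented above.
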