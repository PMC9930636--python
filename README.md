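# tempostab

Temporal stability of dynamic functional connectivity (dFC) from
parcellated BOLD time series.

Functional brain networks reorganize on the timescale of seconds. Most
time-resolved connectivity analyses cluster windowed correlation matrices
into discrete "states"; `tempostab` instead follows an unsupervised,
window-free route and asks a quantitative question: *how stable is the
dominant connectivity pattern over time, and how does that stability differ
between task and rest, across brain networks, and over the adult lifespan?*
It is written for researchers who already have region-by-time BOLD matrices
(e.g. AAL-parcellated resting-state or task fMRI) and want per-subject
stability matrices, scalar summaries, and cohort-level statistics.

## Method

For a region-by-time signal `s(n, t)` with N regions:

1. **Instantaneous phase.** Each region's zero-meaned series is extended to
   an analytic signal `z(t) = s(t) + i H[s(t)]` (Hilbert transform);
   `θ(n, t) = arg z(n, t)` is its instantaneous phase.
2. **Phase-coherence dFC.** `dFC(n, p, t) = cos(θ(n,t) − θ(p,t))` — one
   symmetric N×N connectivity matrix per timepoint, no windowing. Each
   slice equals `c cᵀ + s sᵀ` (c = cos θ, s = sin θ) and is therefore
   exactly rank 2.
3. **Dominant subspace.** Eigendecomposition `dFC_t = V S Vᵀ`; the k = 3
   leading eigenvectors (scaled by √λ) form `D_t`, which captures ≥ 99% of
   the slice's variance — in fact all of it, by the rank-2 identity.
4. **Temporal stability matrices.** For every timepoint pair, either the
   largest principal angle `φ(t_x, t_y) ∈ [0, π/2]` between span(D_tx) and
   span(D_ty), or the region-averaged Mahalanobis distance
   `M = √((d_x − d_y)ᵀ C⁻¹ (d_x − d_y))` between matched region rows, with
   C estimated from the rows of `D_tx`. Block structure in the T×T matrix
   exposes dwell epochs of the connectivity pattern.
5. **Summaries.** Shannon entropy (base 2, 256 bins) of the stability
   matrix's value histogram; Frobenius distance between stability matrices
   of different conditions; and an AR(ρ) characterization of the lag-1
   stability time course with the order chosen at the first local minimum
   of `AIC(ρ) = −2L + 2ρ` (ρ = 0 is white noise, ρ = 1 Markovian, ρ > 1
   longer temporal memory).
6. **Cohort statistics.** 5-year age bins and young (18–40), middle
   (41–60), old (61–88) cohorts; Wilcoxon rank-sum / signed-rank
   comparisons with Jarque-Bera and D'Agostino-Pearson normality screening;
   quadratic-in-age ("U-shape") regression of entropy over the lifespan.

A regime-switching synthetic BOLD generator (phase-locked communities with
controllable dwell times, oscillation frequency and noise) provides exact
ground truth for every stage.

## Worked example

```python
import numpy as np
from tempostab import RegimeSpec, TemporalStabilityModel, generate_regime_bold

rng = np.random.default_rng(7)
spec = RegimeSpec.random(116, n_regimes=3, dwell_mean=10, rng=rng)
ts, states = generate_regime_bold(spec, n_timepoints=261, seed=rng,
                                  subject_id="demo")

res = TemporalStabilityModel(ts).fit(metrics=("angle", "mahalanobis"),
                                     compute_ar=True)
print(res.summary())
```

```
Temporal Stability Results
======================================================
subject:            demo  (synthetic)
regions x time:     116 x 261   TR = 2 s
estimator:          phase_coherence
subspace dimension: k = 3
variance fraction:  min 1.000000, mean 1.000000
------------------------------------------------------
       angle: range [0.3528, 1.5708], median 1.4470
              entropy = 6.6566 bits (fixed_theoretical, 256 bins)
              AR order (first local AIC min) = 1
 mahalanobis: range [0.3781, 3.4785], median 2.0639
              entropy = 7.1037 bits (minmax, 256 bins)
              AR order (first local AIC min) = 2
```

Reading the output: the minimum variance fraction of 1.0 confirms that
three components capture each connectivity slice entirely (the rank-2
identity). The angle matrix mixes small within-regime angles with large
between-regime ones — its 6.66-bit entropy reflects that mix; longer dwell
times would concentrate the histogram and lower the entropy. The AR order
of the lag-1 stability course exceeds 0, i.e. the fluctuation of stability
is not white noise. `res.plot_stability("angle")` shows the block-structured
T×T matrix; `res.plot_aic("angle")` the AIC curve.

Cohort-level runs go through `tempostab.run_pipeline` (YAML config or dict)
or the CLI:

```bash
tempostab simulate --out cohort/ --seed 7
tempostab pipeline --config run.yaml
```

producing per-subject stability matrices, `entropy_table.csv`,
`group_tests.csv` and `lifespan_fit.json`.

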