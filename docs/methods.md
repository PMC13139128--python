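# Methods

`leafspec` reimplements a complete hyperspectral inversion workflow for leaf
nitrogen content (% dry mass) in apple: synthetic leaf-reflectance
generation, spectral preprocessing, hybrid wavelength selection, joint X–Y
sample partitioning, four regression models, accuracy metrics, residual
diagnostics, and Shapley-value attribution.  This note records the models,
the defaults and why they are what they are, and what the synthetic results
do and do not show.

## Synthetic leaf spectra

The original orchard spectra are not publicly deposited, so the package
ships a generator (`leafspec.synth`) whose output has the statistical
structure the downstream analysis assumes.

**Nitrogen.** Each phenological stage carries a truncated-normal
description taken from the study's sample statistics — new-shoot stop (NSS):
n = 125, mean 2.479 %, sd 0.201, range [2.035, 2.873]; autumn-shoot stop
(ASS): n = 118, mean 2.795 %, sd 0.248, range [2.235, 3.752].
`sample_nitrogen` draws from normal(mean, sd) truncated to the range;
dataset generation uses a moment-matched variant (loc and scale solved
numerically so the *post-truncation* mean and sd equal the recorded sample
statistics, since plain truncation at ±2σ shrinks the realized sd by ~12 %).

**Reflectance.** Each spectrum on the 1 nm grid 400–2500 nm is

```
r(λ) = clip( a·[ c(λ) · exp(−Σ_k d_k G(λ; μ_k, σ_k)) ] + b + ε(λ), 0.001, 0.999 )
```

where `c(λ)` is a continuum: a visible shelf (0.17) rising through a
logistic red edge to a NIR plateau (+0.38) with a gentle SWIR tilt.  The
red-edge inflection sits at 705 nm and shifts +14 nm per unit of the
chlorophyll latent — the classic red-edge displacement with canopy
nitrogen/chlorophyll status, and the one feature whose information is
positional rather than per-band.  Gaussian absorption profiles `G` sit at
pigment (430/460/680 nm), water (970/1200/1450/1940 nm), protein
(2045/2180 nm) and structural-carbohydrate (2340/2385 nm) centres; the deep
1450/1940 nm water bands produce the troughs and the local maxima near
1700 and 2200 nm seen in real leaf spectra.

Absorption depths are linear in four latent constituent levels, each
`1 + slope·z_N + noise_sd·u` with `z_N` standardized nitrogen:
chlorophyll (+0.40, noise 0.24), protein (+0.45, 0.20), structural
carbohydrates (−0.35, 0.28), water (+0.15, 0.48 — implied correlation with
nitrogen ≈ 0.3).  Pigment and protein absorption therefore deepen — and
NIR/SWIR reflectance falls — as nitrogen rises, while structural
carbohydrate bands move the opposite way.  Per-sample multiplicative/
additive scatter (sd 0.04 / 0.008) and Gaussian sensor noise
(sd 0.002 in the core, blending to 0.008 over the outer 200 nm) sit on
top.  The ASS stage uses its own nitrogen distribution and a 1.25×
structural-depth gain, emulating the autumn shift toward structural
compounds (covariate shift for cross-stage validation).

Widths, depths, latent slopes and noise levels were calibrated once so
that the full default pipeline's test-set R² lands in the 0.6–0.8 regime
reported for the real data, and then frozen.  The generator does **not**
attempt radiative-transfer (PROSPECT-class) realism, instrument artifacts
(detector splices, dark current), or spatial/canopy effects.  Consequently,
passing tests demonstrate that the *algorithms* behave correctly and that
the pipeline recovers signal of realistic strength — not that any model
would achieve a particular accuracy on real orchard spectra.

## Preprocessing

Savitzky–Golay (SG) smoothing and second derivative (SD) use a 15-point
window with a degree-2 polynomial — a common choice for 1 nm resampled
leaf spectra; both are configurable.  Interior points use the classical
convolution weights; within half a window of a band edge the polynomial is
re-fitted on the truncated window, so no reflected or fabricated values
enter the result.  The second derivative is reported per nm² with the grid
spacing explicit, and requires a uniform grid.  MSC regresses each spectrum
on a reference (training-set mean inside modelling, to avoid leakage) and
inverts the fitted affine scatter; SNV standardizes each spectrum with the
m−1 denominator.  The modelling chain is SG → SD, which maximized
band–nitrogen correlations among the four options here as in the original
analysis.

## Wavelength selection (CARS → SPA)

CARS runs N = 50 Monte-Carlo iterations: each fits PLS1 (NIPALS, mean
centring; components chosen by seeded 5-fold RMSECV, capped at 10) on a
random 80 % sample subset restricted to currently retained bands, weights
each band by its normalized |regression coefficient|, keeps the top
`⌈r_i·p⌉` by the exponentially decreasing schedule
`r_i = a·e^(−k·i)` (endpoints: all p bands at run 1, two bands at run N),
and thins them further by weighted sampling with replacement.  The run
whose retained set has minimal RMSECV wins.  SPA then grows, from every
candidate band, a chain of successive orthogonal projections (pick the
column with the largest residual norm against the span of those already
chosen) and scores every (start, length) prefix by multiple-linear-
regression RMSE under seeded 5-fold CV; the minimal-RMSE subset wins, with
ties broken toward fewer bands.  A floor (`min_vars`, default 8) keeps
enough bands for the CNN's two pooling stages.  Selection runs on training
rows only; a `paper_mode` switch scores SPA subsets on the held-out test
set instead, mirroring the original protocol at the cost of leakage.
The published 15-band selection for the real NSS data ships as a JSON
fixture (`leafspec.selection.load_reference_wavelengths`).

## Sampling

Outliers: spectra are projected onto principal components covering 95 % of
variance (≤10 PCs), squared Mahalanobis distances computed in score space,
and samples beyond the χ²(1−α, k) quantile flagged in a single pass
(α = 0.025).  Splitting: SPXY — Kennard–Stone max–min selection on
`d_x/max(d_x) + d_y/max(d_y)` with Euclidean spectral and absolute
nitrogen distances; train size `round(0.6·n)` (75/50 at n = 125); ties
break toward the lowest sample index so the split is bit-reproducible.

## Models

All four regressors share a `fit → ModelBundle → predict` contract and
never see test targets during fitting (the PSO `paper_mode` fitness is the
single flagged exception).

* **RF** — 300 trees, depth ≤ 8, ≥ 3 samples per leaf (scikit-learn).
* **SVM** — RBF SVR on feature-standardized inputs; (C, γ) from seeded
  5-fold CV over the integer-exponent grids 2⁻⁵…2⁹ × 2⁻¹⁵…2¹;
  ε = 0.01.
* **CNN** — a numpy implementation of the fixed architecture
  Conv(8 kernels, 3×1, same) → ReLU → MaxPool → Conv(8, 3×1) → ReLU →
  MaxPool → Dropout(0.5) → FC(32) → ReLU → Linear(1), trained with Adam
  (initial rate 0.001, decay ×0.1 on validation plateau with a 1e-5
  floor), decoupled L2 weight decay (λ = 0.001), batch 32, up to 500
  epochs, early stopping (patience 150) on an internal seeded 20 %
  validation fold with best-weights restore; the early-stop signal is a
  9-epoch moving average because a ~15-sample fold is too noisy raw.
  Backpropagation is verified against finite differences in the tests.
* **PSO-CNN** — global-best PSO (20 particles, 15 iterations, w = 0.729,
  c1 = c2 = 1.49445, velocity clamp at half the box, reflecting bounds)
  over log-scaled learning rate [5e-4, 1e-2], log2-scaled batch size
  [16, 512] (rounded, clamped to n_train) and log-scaled λ [1e-4, 1e-1].
  Fitness is the RMSE of a freshly trained CNN on an inner validation fold
  (20 % of training rows); under `paper_mode` the held-out test set drives
  fitness instead, as in the original description.  Particle 0 starts at
  the baseline hyperparameters, so the swarm's best can never rank worse
  than the baseline on the fitness fold; the final model retrains at the
  best hyperparameters with the baseline's seed policy, so selecting the
  baseline configuration reproduces the baseline CNN exactly.

Two training-protocol choices deserve emphasis.  *Pooling geometry* is not
specified beyond "max pooling": with only ~15 input bands, two size-2
stride-2 stages collapse the sequence to three positions and measurably
hurt accuracy, so the default is size 2 with stride 1 (overlapping); the
stride is configurable.  *Restart averaging*: a single small network
trained on 60 rows is dominated by initialization noise, so `cnn_fit`
averages the predictions of 5 independently seeded training runs — the
same spirit as the original convergence figures, which report means over
10 independent runs.  Both choices apply identically to the baseline CNN
and the PSO-CNN, keeping the comparison fair.

## Evaluation

R² = 1 − SSE/SST and RMSE = √(SSE/n).  Two RPD variants are reported:
`rpd_conventional` = sd(observed; n−1)/RMSE, the form spectroscopists
grade against (<1.4 poor, 1.4–2.0 moderate, >2.0 strong), and `rpd_paper`,
which follows the source formula verbatim with *predicted* deviations from
the observed mean in the numerator.  They coincide exactly only for
perfect predictions; both are always emitted because it is genuinely
ambiguous which form produced the published values.  Residual diagnostics
report the ±1 sd coverage (boundary-inclusive, n−1 sd), a 20-bin histogram
with fitted-normal ordinates, and normal Q–Q pairs at Blom plotting
positions, scaled so that exactly normal residuals fall on the identity
line.  Cross-stage validation applies a fitted bundle to an
independently generated ASS dataset after identical SG–SD preprocessing
and band subsetting, and adds the OLS slope of predicted vs observed.

## Shapley attribution

The coalition value of a subset S is the model prediction with features
outside S replaced by a fixed baseline (training-set column means) — the
single-reference formulation, not marginal integration over the data
distribution; that is a stated limitation.  The exact estimator enumerates
all 2^p coalitions per sample with cached predictions (default at p ≤ 16;
32 768 evaluations per sample at p = 15) and satisfies the efficiency,
symmetry and dummy axioms to numerical precision; a seeded
permutation-sampling estimator with per-value standard errors covers
larger p.  Beeswarm exports colour points by raw reflectance at each band,
the conventional reading of "high/low feature value", while the attribution
itself acts on the model's actual SG-SD inputs.

## Numerical choices and degenerate inputs

Constant spectra are rejected by SNV/MSC with the offending sample named
(with a relative floor, since a numerically constant row has rounding-level
sd).  Zero-variance wavelength columns screen to r = 0 with a warning.
PLS stops extracting components when the residual covariance vanishes.
The CARS retained-count `⌈r_i·p⌉` subtracts 1e-9 before the ceiling so the
analytically exact endpoints (p and 2) are not rounded up.  SPA truncates a
chain when the best residual norm drops below 1e-10 (rank deficiency).
Non-finite CNN training loss aborts with diagnostics rather than returning
a silent NaN model.  Every stochastic step derives its seed from a global
seed via SHA-256 of a stage label (`derive_seed`), so runs are
reproducible end to end in a single-threaded process.

## Problem sizes used in the shipped checks

The test suite exercises the generator at the recorded stage sizes
(n = 125 / 118), the selector-recovery simulation at 80 × 500 with five
planted bands over ten seeds, the outlier-rate simulation at n = 10⁴, the
residual-coverage simulation at n = 10⁵, and the end-to-end battery at
five seeds of the full default pipeline (all four models per seed).

## Known limitations

* The generator's near-additive band–nitrogen relation makes depth-8
  random forests and grid-tuned RBF-SVMs sit close to the attainable
  accuracy ceiling.  Under these conditions the fixed two-conv-layer CNN
  trails RF/SVM on most seeds (battery means: RF 0.77, SVM 0.74,
  CNN 0.60, PSO-CNN 0.64), i.e. the real-data finding that the CNN family
  dominates the classical models does not transfer to this synthetic
  benchmark; an equally sized dense network probe confirms the gap is the
  convolution/pooling front-end, not the optimizer.
* Single-reference SHAP ignores feature dependence; attributions at
  strongly correlated bands should be read jointly.
* CNN/PSO-CNN reproducibility is guaranteed under single-threaded numpy;
  exotic BLAS threading could reorder reductions.
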