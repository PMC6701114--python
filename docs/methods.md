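# Methods

## The screening model

For each pair of one microbial taxon (response `y`, relative abundance in
[0, 1]) and one immune readout (predictor `x`, continuous and positive), we
fit by ordinary least squares the full model

    y = β0 + Σ_c β_c · 1[cohort = c] + β_x · x + Σ_c β_cx · x · 1[cohort = c] + ε

under treatment (reference-cell) coding: a user-designated reference cohort
is absorbed into `β0` and `β_x`, and each of the K−1 non-reference cohorts
contributes an intercept offset `β_c` and a slope offset `β_cx`. The
reduced model keeps only the intercept and cohort indicators. With K
cohorts and n samples the full model has 2K parameters and the reduced K,
so the partial F-test has numerator degrees of freedom K and denominator
df = n − 2K:

    F = [(RSS_reduced − RSS_full) / K] / [RSS_full / (n − 2K)]

The test asks whether the immune readout carries any explanatory value for
the taxon once cohort means are accounted for — via a common slope, via
cohort-specific slopes, or both. Per-cohort fitted lines follow from the
coefficients: cohort c's slope is `β_x + β_cx` (with `β_cx = 0` for the
reference) and its intercept `β0 + β_c`.

Interaction inference: for each non-reference cohort, the two-sided t-test
of `β_cx = 0` (standard error from the unscaled covariance diagonal scaled
by `RSS_full/df`) asks whether that cohort's slope differs from the
reference cohort's. We report two-sided p-values; the direction is visible
in the fitted-line geometry.

Assumptions inherited from OLS: independent homoscedastic errors within the
pair's regression, linearity of the microbe–readout relationship within
each cohort, and n large enough that the F reference distribution is
adequate. Relative abundances are treated as independent responses; no
compositional constraint is imposed (see Limitations).

## Multiple testing and the top table

All (microbe, immune) pairs are attempted in deterministic manifest order.
Pairs whose fit is degenerate — singular design (e.g. the readout constant
within every cohort), constant response, or an exactly interpolating full
model — are excluded with a logged reason. The Benjamini–Hochberg step-up
runs over the p-values of all non-degenerate fits (m = number of computed
tests, not the pre-filter pair count: only performed tests are corrected).
The top table keeps pairs with p (or BH-adjusted p) **strictly below** the
configured threshold, sorted by p ascending with (microbe, immune)
lexicographic tie-break for determinism, and keyed 1..R after sorting. Both
raw-p and FDR thresholds are supported because realistic screens use
either, depending on how exploratory the follow-up is.

## Influence diagnostics

DFFITS for observation i is the standardized change in the i-th fitted
value when observation i is deleted:

    DFFITS_i = e_i √(h_i / (1 − h_i)) / (s_(i) √(1 − h_i)),
    s_(i)² = (RSS − e_i²/(1 − h_i)) / (df − 1)

computed in closed form from full-model leverages `h` and residuals `e`
(the leave-one-out refit version exists only as a test oracle; the two
agree to 1e−10 relative on all fixtures). Observations with zero residual
get DFFITS = 0 by convention. `maxInfluence = max |DFFITS_i|` is carried in
the top table so relationships driven by one sample are visible at a
glance; when df ≤ 1 the deletion fit is undefined and diagnostics are
skipped with a warning.

## Data preparation

* **Prevalence filter**: microbe features are kept when strictly positive
  in at least `min_nonzero` samples (inclusive boundary). Immune features
  are never filtered.
* **Transform**: an optional elementwise square root of all immune
  readouts compresses dynamic range and dampens extreme values; it is
  applied before fitting, and exported sample-level values are
  post-transform so plots match the fitted models.
* **Missing values** are dropped pairwise (per pair, not globally), which
  preserves the maximal n for each independent fit. How missing readouts
  should be handled is genuinely open; pairwise deletion is this package's
  choice and each fit records the n it used.

## Synthetic data

The generator emulates small cohort studies of this design: 2–4 cohorts of
roughly 9–20 samples each, microbial relative abundances, positive
continuous immune readouts. Null microbes are zero-inflated: zero with
probability `zero_inflation_prob` (default 0.3), otherwise
Beta(1.5, 8)-distributed (low abundances, right-skewed). Immune readouts
are i.i.d. log-normal on a unit-free positive scale, default
LogNormal(−0.7, 0.5) (median ≈ 0.5). Planted microbes are per-cohort
linear functions of one immune partner plus Gaussian noise (default sd
0.02 on the abundance scale, baseline 0.1), clipped into [0, 1] with the
clipped fraction reported in the truth record; a specification that clips
more than half of a planted feature's values is rejected as unrealistic
for the unit interval.

Two design constraints matter:

* **Clipping must stay rare.** The generating model is linear precisely so
  that parameter recovery is well defined; the default immune scale places
  the clipping boundary for slopes up to ~0.4 at roughly three log-normal
  sigmas. Even 1–2 clipped points per dataset bias a low-noise slope fit
  by many standard errors.
* **What the generator does not emulate**: compositional renormalization
  across taxa (taxa are independent), measurement error in the readouts,
  within-subject correlation, and covariates such as age or sex. Passing
  tests therefore demonstrate correctness of the screening machinery under
  its own assumptions, not robustness to these real-data features.

A screen of generated data can be scored against the truth record
(`evaluate_screen`), giving realized power and false-discovery proportion.
One empirical property worth knowing: when a planted microbe is screened
against the *other* immune readouts, those null regressions inherit
skewed, possibly heteroscedastic residuals from the planted signal, and
the F-test's small-p tail inflates somewhat. With symmetric planted slopes
(±0.3) the realized FDP at BH 0.05 averages ≈ 0.08 rather than the nominal
≤ 0.05 — still controlled, but a reminder that the linear screen's error
control degrades as the error distribution departs from normality.

## Numerical choices

* OLS via thin QR decomposition; the design is declared singular when the
  smallest |R_jj| falls below 1e−10 of the largest. Leverages come from
  the Q factor, coefficient covariances from R⁻¹R⁻ᵀ.
* Residual sums of squares at the level of accumulated rounding error
  (below `(1e−12 · max|y|)² · n`) are treated as exact zeros: if the
  reduced model is already numerically perfect the models coincide (F = 0,
  p = 1); if only the full model interpolates, the pair is flagged
  degenerate-perfect and excluded (no residual scale exists for
  inference).
* BH adjustment is the vectorized step-up with a reverse cumulative
  minimum; it is permutation-equivariant and elementwise ≥ the input.
* Glyph normalization maps all cohorts' fitted segments into the unit
  square by the shared min/max of x and of the fitted values at segment
  endpoints; zero-width ranges map to the 0.5 midline.
* The report's network layout is a force-directed (spring) embedding with
  a fixed iteration count (60) and seeded initialization, so identical
  documents and seeds give identical coordinates.

## Problem sizes used in the checks

The bundled checks run entirely on generated data: the three study-scale
screens (43×17, 70×6 with four cohorts, 54×103), a 5562-pair global-null
calibration (binomial 3σ band around 0.05), 100-replicate
planted-recovery studies with 8 planted among 200 pairs, and 500-replicate
slope-recovery simulations. These sizes keep the full suite under a minute
of compute while leaving the binomial bands tight enough to be
informative.

## Known limitations

* One model form for all pairs; no per-pair model selection, no negative
  binomial or zero-inflated response models even though abundances are
  bounded and zero-inflated — the linear screen is a hypothesis generator,
  not a final analysis.
* Microbe is always the response and the immune readout the predictor;
  there is no option to swap.
* No covariate adjustment beyond cohort.
* FDR control is nominal under the model assumptions; skewed or
  heteroscedastic residuals inflate it (measured above).
* The exported JSON schema is this package's own documented format; no
  external viewer compatibility is asserted.
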