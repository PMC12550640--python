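# Methods

This note documents the models implemented by `fusionern`, the conventions
behind the EEG-fMRI fusion computation, the synthetic-cohort generator, and
the numerical choices that matter when interpreting output.

## ERN measurement

Epoched EEG around the button response is baseline-corrected per trial and
channel (default window −100..0 ms), averaged within condition
(incongruent-error vs incongruent-correct), and differenced. The ERN peak
is the **most negative frontocentral cluster mean** of the difference wave
within a search window (default 0–100 ms post-response); "maximal" is read
as greatest negative polarization because the ERN is a negative-going
component. Ties are broken by the earliest sample so output is
deterministic. The peak latency selects the CDR map used downstream and is
recorded as provenance. The cluster channels, windows and minimum trial
counts are configuration, not constants: source datasets differ and the
defaults (Fz/FCz/Cz, 0–100 ms) are ordinary choices for response-locked
error signals.

## EEG-fMRI fusion

The EEG source model is a tetrahedral mesh with one current-density (CDR)
value per element and condition; subtracting correct from error maps gives
the CDR-difference map of error-specific activity. The fMRI side is an
error-minus-correct contrast on a voxel grid with a RAS affine (3 mm voxels
by default, no interpolation). Because the two samplings differ in
resolution, not every voxel meets an element and vice versa; "overlap" is
operationalized as **voxel-centroid containment** in a tetrahedron,
decided by barycentric coordinates with tolerance 1e-9. When a centroid
lies exactly on a shared face, the lowest element index wins — an
arbitrary but deterministic rule. The fusion value of a mapped voxel is
`contrast(voxel) × cdr_difference(element)`; unmapped voxels are treated
as **undefined, not zero** (zero-filling would bias ROI means toward 0).

ROI summaries are arithmetic means: over labeled voxels (fMRI), over
labeled voxels with a defined fusion value (fusion), and over elements
whose centroid falls in a labeled voxel (EEG) — the element rule mirrors
the voxel rule. An empty contributing set yields a missing score with the
count reported, never a silent zero, and a fusion score exists only where
both constituent modalities do.

## Latent change score models

All structural models run on one engine: LISREL-style matrices
(`mu = nu + Lambda(I−B)^{-1}alpha`,
`Sigma = Lambda(I−B)^{-1}Psi(I−B)^{-T}Lambda^T + Theta`) with free, fixed
and equality-labelled cells, estimated by casewise (full-information)
maximum likelihood so incomplete cases contribute their observed
subvectors. Cases are grouped by missingness pattern; the grouped
likelihood is identical to the casewise sum.

**Anxiety LCS.** Six indicators (parent SCARED, child SCARED, binary
diagnosis × two waves) measure latent anxiety at 13 and 15. Parent SCARED
is the fixed-unit, zero-intercept marker; the other loadings *and
intercepts* are constrained equal across waves (the intercept constraint
is needed to identify the mean structure alongside loading invariance).
The wave-15 factor is `eta_13 + delta` with free means, variances and
covariance for `eta_13` and `delta`. 15 free parameters against 27
observed moments leave 12 df. The binary diagnosis is treated as a
continuous 0/1 indicator under normal-theory ML; its loading is freely
estimated, so misspecification mostly costs efficiency, but users should
expect mild attenuation relative to a proper threshold model.

**Neural LCS.** One observed ROI score per wave, residual variances fixed
at zero — the model is then the FIML-consistent version of the classical
difference score: with complete data the change-factor mean equals the
sample mean of (wave15 − wave13) exactly, while subjects with a single
observed wave are retained and receive conditional (shrunken) factor
scores, flagged `*_model_based` in the change-score table. The
standardized change mean is `mean(delta)/sd(delta)`.

**Factor scores** are regression (conditional-mean) scores computed per
missingness pattern; Bartlett scores are available as an option but are
ill-defined under zero residual variances. A latent with no correlated
observed information in a case's pattern scores as missing.

## Blockwise incremental validity

Predictors enter in four ordered blocks — (sex, minority status, BI,
baseline anxiety), then EEG, fMRI and fusion scores with their BI
products — and the outcome is the latent anxiety-change factor with its
measurement model embedded (an observed proxy column can be substituted,
which is also how the least-squares oracle equivalence is defined and
tested). Observed predictors are promoted to phantom latents (unit
loading, zero residual) with a saturated covariance structure, and the
outcome regression on all predictors is saturated too, which makes the
fitted model maximum-likelihood equivalent to any phantom-variable
reparameterization of the same blocks. The block quantities are therefore
read off the implied joint moments:

* `gamma_k` = semipartial multiple correlation of block k after removing
  blocks 1..k−1 (the hierarchical increment's square root),
* `delta R^2_k = gamma_k^2`, with cumulative R² non-decreasing,
* delta-method standard errors from the observed-information covariance,
* the test of `gamma_k = 0` as the joint Wald statistic on block k's
  semipartial coefficients. The statistic is referred to
  `F(m, n − p − 1)` via `F = W(n−p−1)/(nm)` (p = total predictors), the
  analogue of the least-squares partial F-test; the plain chi-square
  reference is measurably anticonservative for later blocks at n = 176
  (9.2% type-I at nominal 5% in 400-replicate null simulations, vs
  3.0–5.5% for the F reference).

On complete data with an observed outcome the increments equal
hierarchical OLS increments to numerical precision — this equivalence is
the normative definition of the parameterization and is enforced by test.
Predictors are z-scored (sample moments) before entry and BI products are
formed after z-scoring, so ±1 SD moderator arithmetic is exact; missing
scores yield missing products.

**Small-sample behavior worth knowing.** The ML plug-in `delta R^2` of an
8-predictor block at n = 176 is biased upward by roughly `m(1−R²)/n`
plus a cross-block term when blocks correlate; with the latent outcome the
inflation is larger still because the outcome's location in indicator
space is partly free. In recovery simulations at the default generating
values (true increments 0.54/0.01/0.01/0.25), 200-replicate means are
≈ 0.55 / 0.08 / 0.09 / 0.25: the covariate and fusion blocks recover
well, the two small nuisance blocks sit ≈ 0.07–0.08 above their true
0.01. The estimator is consistent (the gap shrinks to ≈ 0.01 by
n = 2000) and no bias correction is applied, because the plug-in is what
the blockwise parameterization estimates.

## Focused path model and simple slopes

The final model regresses the latent anxiety-change factor on the
covariates, latent baseline anxiety, one modality's four ROI scores and
their four BI products (default modality: fusion; an extra covariate such
as maternal education can be appended). Coefficients are reported
unstandardized (B, SCARED-change points per predictor SD) and
standardized (β). Simple slopes at moderator values m ∈ {−1, 0, +1} SD
are `b_focal + m·b_interaction` with delta-method variance
`Var(b_f) + m²Var(b_i) + 2m·Cov(b_f, b_i)`; `plot_simple_slopes` draws
the crossover.

## Synthetic cohort generator

The generator is the package's study-design stand-in and is first-class,
tested code. Defaults encode the target cohort: n = 176, 52.3% female,
24.4% racial/ethnic-minority status, BI standard normal, latent baseline
anxiety N(22, 49) in SCARED units correlated 0.25 with BI, change factor
with mean −0.76 and variance 14.30, SCARED indicators generated
continuously then rounded and clipped to [0, 82] (clipping < 1% at the
defaults), diagnosis from a logistic link with ≈ 20% prevalence. Neural
ROI activations are two-wave (level, change) Gaussians; the fusion-dACC
change mean/variance (0.17, (0.17/0.37)²) make the generating
standardized change 0.37 (PCC: 0.43). Cross-correlations use a Kronecker
construction: modality correlations (EEG–fMRI 0.3, fusion 0.5 with each
constituent) times a region/type block (dACC–PCC 0.3, level–change −0.2),
guaranteed positive semidefinite.

For the geometry route, signals are planted so the downstream ROI means
recover the truth exactly at zero noise: in-ROI elements carry the EEG
truth in the error-condition CDR, in-ROI voxels the fMRI truth, and the
fusion ROI mean recovers their product (the fusion "truth" in this
generator). The default ROI boxes are aligned with the mesh-cube lattice
so each ROI is tiled by whole elements; every cube splits into five
tetrahedra with alternating parity, so the box is tiled conformally and
every voxel centroid is inside some element. Epoched EEG plants a
negative Gaussian deflection at 50 ms on the frontocentral channels of
error trials, with amplitude proportional to the subject's true EEG-dACC
activation.

Missingness is **MAR by construction**: per modality and wave, a session
goes missing with probability logistic in (sex, minority, BI), with the
intercept calibrated numerically so the marginal rate matches its target
(default 0.14 per modality-session, +0.7 log-odds for minority status,
giving ≈ 25% average missingness across neural score columns and the
documented pattern that fusion scores — requiring both sessions — are
missing most often). MNAR mechanisms are out of scope.

Two purpose-built cohorts support the recovery studies. The
*incremental* generator builds the change factor from block-orthogonalized
composites so the population hierarchical increments equal the configured
sequence exactly (verified against large-n least squares); within-block
signal composition follows the focused path-model pattern. The *path*
generator draws z-scored fusion predictors and sets coefficients to the
reference values; because interactions of that size imply an outcome scale
far beyond the questionnaire range, its indicators stay continuous
(unclipped) — clipping would distort the very measurement structure the
study probes. Replicate r of any study uses seed `base + r`.

What the generator does **not** emulate: realistic lead fields or
hemodynamics, non-Gaussian anxiety distributions, MNAR attrition,
practice/retest effects, or site/scanner variance. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generating process, not robustness to real-data pathologies.

## Numerical choices

* Optimization: L-BFGS-B on the total FIML deviance with analytic
  gradients (chain rule through the LISREL matrices), preconditioned by a
  closed-form complete-data Fisher-information diagonal — without it the
  474-parameter incremental model needs thousands of iterations; with it,
  tens to hundreds. Convergence: relative deviance change < 1e-11 and
  projected gradient < 1e-5 (scaled); up to 5 seeded jitter restarts on
  failure, and results carry an explicit `converged` flag.
* Free variance parameters are bounded below at zero. Unbounded fits
  produced Heywood cases (negative latent residual variance, cumulative
  R² > 1) in roughly a tenth of incremental-model replicates; boundary
  solutions are visible in the parameter table as exact zeros.
* Start values: saturated FIML moments (EM algorithm, eigenvalue-floored
  when n < p) for covariance parts, moment/regression solves for
  structural parts, simple defaults elsewhere (loadings 1, residuals at
  half the sample variance).
* Standard errors: inverse observed information via central differences
  of the analytic gradient; pseudo-inverse with a warning when singular.
  95% CIs are ±1.96·SE and p-values use the normal reference.
* Fit indices are the plain ML χ²-based RMSEA
  (`sqrt(max(χ²−df,0)/(df(n−1)))`), CFI against the independence model,
  and SRMR over standardized covariance *and* mean residuals computed
  against the saturated FIML moments; robust variants are not
  implemented. Just-identified models report indices as not applicable.
* Non-PD parameter regions during optimization return a finite penalty
  sloping back toward the start, so line searches recover.
* Degenerate inputs: zero-volume tetrahedra, cyclic structural matrices,
  unscaled latents, all-missing rows, empty ERP conditions and
  zero-variance z-score inputs are all rejected with named errors; empty
  ROI sets propagate as missing values.

## Known limitations

* The binary diagnosis indicator under normal-theory ML and the clipped,
  rounded SCARED scores leave a small systematic offset in the
  incremental-R² recovery even at large n (≈ +0.02 on the covariate
  block at n = 4000).
* The blockwise `delta R^2` plug-in bias at n = 176 described above.
* Robust (sandwich / Satorra-Bentler) corrections, WLSMV estimation for
  categorical indicators, and >2-wave change models are not implemented.
* The voxel-element tie rule and the centroid-containment definition of
  overlap are documented conventions; partial-volume weighting is not
  attempted.
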