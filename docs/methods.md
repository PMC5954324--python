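# Methods

## Signal model and simulation

Each tissue is a discrete set of water pools `(f_j, T2_j)` with fractions
summing to one. The noise-free multi-echo magnitude signal is

    S(TE) = S0 · Σ_j f_j · exp(−TE / T2_j),

sampled by default at 32 echoes, TE = 10, 20, …, 320 ms (a whole-cerebrum
GRASE protocol; TR is carried as metadata only — the model ignores
longitudinal recovery). The default tissues are three-pool:

| pool | T2 (ms) | NAWM fraction | lesion fraction |
|---|---|---|---|
| myelin water | 20 | 0.0999 | 0.080 |
| intra/extracellular water | 80 | 0.8801 | 0.900 |
| free water | 2000 | 0.02 | 0.02 |

The pool T2s sit centrally inside the short (15–40 ms), medium
(40–200 ms) and long (>1500 ms) spectral windows; no pool is placed in
the unlabelled (200, 1500] ms band. Ground-truth MWF is the short-window
fraction of the pool fractions, so NAWM truth is 0.0999 and lesion truth
0.080 by construction.

Phantom geometry is deliberately minimal: a cuboid "brain" of NAWM with
spherical lesions, because the quantities under test (spectrum fitting,
window fractions, mask algebra, ROI means) are geometry-free and spheres
give exact voxel-count oracles. Noise is additive Gaussian by default
(`noise_sigma` in units of `S0`, so SNR = S0/σ); a Rician option forms the
magnitude of a two-channel complex signal, which converges to the
Gaussian model at high SNR (mean magnitude bias of a constant signal is
σ²/2S ≈ 0.02 % at SNR 50). What the phantoms do **not** emulate: partial
volume gradients, B1/flip-angle errors and stimulated echoes, spatially
correlated noise, anatomy. Passing recovery tests therefore demonstrate
the correctness of the estimator chain, not in-vivo accuracy.

## NNLS spectrum fitting and MWF

The spectrum is resolved on a fixed grid of T2 times (default 40
log-spaced points spanning 15–2000 ms) through the design matrix
`A_ij = exp(−TE_i/T2_j)`. Amplitudes solve `min ‖A s − y‖₂, s ≥ 0` with
an exact active-set solver; maps are bit-reproducible because nothing is
randomized. MWF is the amplitude sum over [15, 40) ms divided by the sum
over [15, 2000] ms. Window edges are half-open so the shared 40 ms
boundary counts once (in medium); points in (200, 1500] ms count toward
the total denominator but no labelled component. A voxel whose total
amplitude falls below 1e−12 × the volume's median in-mask signal is
marked undefined (NaN) and excluded from ROI means, never reported as 0.

An optional χ²-constrained mode returns the minimum-energy non-negative
solution whose data misfit equals `chi2_factor` (default 1.02) times the
unregularized minimum, found by bisection on a Tikhonov weight (relative
tolerance 1e−6, hard failure after 100 iterations). `chi2_factor = 1`
reproduces the plain fit. Regularization is **off** by default; it
reduces the voxelwise variance of MWF (verified by simulation) at the
cost of additional downward bias in the short-T2 fraction.

### Known limitation: short-T2 bias at moderate SNR

At SNR 100, voxelwise unregularized NNLS underestimates the short-window
fraction: on the default phantom the NAWM ROI mean is ≈0.082 against a
truth of 0.0999 and the lesion mean ≈0.066 against 0.080. The mechanism
is visible in the fitted spectra: in ~17 % of voxels the noise lets the
solver merge the myelin-water pool into the intra/extracellular pool
(short mass exactly 0, a one-sided error the non-negativity constraint
cannot balance), and in others spike positions wander across the 40 ms
window edge. The bias is intrinsic to the estimator, not the solver: the
residual matches exhaustive active-set enumeration to 1e−10, noise-free
on-grid signals are recovered exactly, and the bias is insensitive to
grid density (12–120 points) and persists at SNR 200. The lesion/NAWM
MWF **ratio** is much more robust (both ROI means share the bias, which
largely cancels: ≈0.808 estimated vs 0.801 planted), which is itself an
argument for the ratio as the subject-level summary. The per-ROI
accuracy check in the acceptance suite documents this bias as a failing
assertion rather than hiding it.

## ROI analysis

Masks are binary volumes in register with the map (affines must agree to
1e−4; nonzero values other than 1, e.g. 0/255 exports, are coerced with a
warning). The lesion mask is subtracted from the NAWM mask before any
statistics so the ROIs are disjoint. ROI statistics are the mean and
standard error of defined map voxels; volume is voxel count × voxel
volume. Registration itself is out of scope — inputs must be pre-aligned,
and the affine check is the guard.

Inter-rater reliability uses ICC(2,1): single measures, absolute
agreement, two-way random effects, computed from the ANOVA mean squares
with F = MS_targets/MS_error on (n−1, (n−1)(k−1)) degrees of freedom.
Absolute agreement is the appropriate form for "would two raters produce
the same number", since it penalises systematic offsets; the
implementation is cross-checked against an independent ANOVA-based
oracle in the tests.

## Cohort statistics

The primary outcome is ΔTUG = Day 10 − Day 1 (negative = improvement).
Missing follow-ups are excluded pairwise; nothing is imputed. Shapiro-
Wilk (α = 0.05) gates parametric vs non-parametric branches: the screen
uses Pearson correlations unless normality is rejected for either
variable of a pair, then Spearman. Four candidate predictors (lesion
volume, lesion MWF, NAWM MWF, MWF ratio) are screened against ΔTUG on
complete cases per predictor; all four results are reported and the
smallest screen p advances to a simple OLS regression (R², F(1, n−2),
F = t² of the slope). The selection rule had to be made explicit; the
smallest-p rule is the natural reading of an exploratory screen. No
multiple-testing correction is applied, matching the exploratory design;
with four predictors at n ≈ 14–16 the winner's p should be read
accordingly. Multiple regression is deliberately out of scope at these
sample sizes. Paired comparisons report Cohen's d = mean difference / SD
of differences, df = n_pairs − 1, and raise on zero-variance differences
rather than reporting an infinite effect size.

Reproduction checks against the packaged demonstration cohort round
half-up at each statistic's printed precision, since printed tables
round ties away from zero (e.g. a mean of 12.75 s prints as 12.8).

## Synthetic cohort generator

Per subject: `nawm_mwf ~ N(0.0999, 0.012)`, `mwf_ratio ~ N(0.80, 0.10)`
clipped to (0, 1.5], `lesion_mwf = ratio × nawm_mwf`,
`tug_day1 ~ N(12.8, 3.9) s`, and
`ΔTUG = β0 + β1·ratio + ε`, `ε ~ N(0, σ_e)`, with Day 10 = Day 1 + ΔTUG
floored at 1 s to keep times physical. Defaults β1 = −17 s per unit
ratio, β0 = 12.5 s give a mean ΔTUG of ≈ −1.1 s at the mean ratio, and
σ_e = 2.5362 s calibrates the planted association to population
R² = β1²σ_x²/(β1²σ_x² + σ_e²) = 0.31 (`calibrate_noise_sd` solves this
for any target). The negative slope encodes "less myelin disruption →
larger mobility gain". Ages, EDSS and lesion volumes are realistic
nuisance covariates (47 ± 13 y; 0–8 in 0.5 steps; log-normal around
7000 mm³) with no planted link to the outcome. At n = 14 the median
fitted R² across seeds is ≈0.33 — slightly above the population value, as
expected for small-sample R² — and sits comfortably within ±0.05 of 0.31.

The screen's selection-consistency property (the planted predictor wins)
is demonstrated at a strongly detectable effect (population R² = 0.6,
win rate 100 % over 200 seeds). At the study-scale effect (R² = 0.31,
n = 16) the win rate is only ≈78 %: with three null predictors at this
sample size, chance correlations regularly beat the true one — a useful
reminder of how fragile small-sample predictor selection is. Under fully
null predictors the selection is uniform within binomial error.

## Numerical and interface choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixed seed ⇒ bit-identical phantoms,
  cohorts, maps and manifests (timestamps aside).
* Echo times live in a JSON sidecar because NIfTI-1 has no standard
  field for them; an echo-count mismatch between image and sidecar is a
  hard error.
* MWF maps are float32 NIfTI-1 with NaN for undefined voxels.
* Problem sizes in the tests and the acceptance script (phantoms of
  ~2 400 voxels, 500–1000 cohort seeds) were chosen as the smallest
  scales at which the recovery statistics are stable; all are
  parameters, not limits of the method.
* No EPG/stimulated-echo correction and no spatial regularization are
  implemented; both are documented limitations rather than silent
  assumptions.
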