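# Methods

## Scope

`germclock` implements a complete desk-scale version of a sperm-methylome
aging study: cohort simulation with known ground truth, purity screening,
a three-level differential-methylation screen, an elastic-net age clock
(with and without BMI as a feature), the GLAD age-acceleration statistic,
and the paired comparison of the two clocks. All inputs are synthetic; the
generator is first-class, tested code, and the statistical machinery is
agnostic to where the β matrix came from.

## Generative model

The cohort is drawn cell by cell from a stratified design: four age
categories × two BMI sub-categories × `n_per_cell` (default 12, i.e. 96
men). Ages and BMIs are uniform within their category's interval. The
open-ended categories are given finite bounds: ">48" is capped at 70 years
(the study-eligibility ceiling) and high/obese BMI at 42 kg/m², which puts
the cell mean near 36 — the range reported for high-BMI fertility-clinic
cohorts. The "30" category spans [30, 31). Semen-parameter columns
(motility, concentration, viability) are cosmetic draws near typical clinic
values, respect the 10 million/ml eligibility floor, and never feed any
computation.

Methylation is generated on the M scale (M = log2 β/(1−β)):

    M_ij = μ_j + a_j · e_i + ε_ij,   ε_ij ~ N(0, noise_sd²)
    e_i  = age_i + b · 1[high BMI]          (injected epigenetic age)

- μ_j ~ N(0, 2) per CpG (`baseline_logit_mean_sd`), giving a realistic
  U-shaped β distribution after the inverse logit;
- a_j is zero except in the `n_clock_regions` clock regions, where one
  slope per region, a_r ~ N(0, `age_slope_sd`), is shared by all member
  CpGs — regional methylation drifts coherently with age;
- b is `bmi_acceleration_years`, the age-acceleration effect under test;
- β = inverse-logit2(M), clamped to [1e−6, 1−1e−6] so the logit stays
  finite.

The marker region holds 14 extra CpGs with μ = logit2(0.005) (sperm
signature ≈ 0) and no age effect; the somatic contamination profile is the
inverse logit of the baseline intercepts with the marker CpGs set to 1.0,
so any 50/50 sperm/somatic mixture lands strictly above the default 0.5
purity threshold. `spike_contamination` mixes that profile into chosen
samples as (1−f)·β_sperm + f·β_somatic.

One master seed expands into per-stage substreams (intercepts, slopes,
noise), so every stage is independently reproducible, and a `GroundTruth`
can be re-used to generate a second cohort "measured on the same array"
(same intercepts and slopes, fresh noise) — e.g. an evaluation cohort for
a clock trained elsewhere.

### Default calibration

Defaults are 6,000 CpGs in regions of 100 (60 regions, 51 of them clock
regions) plus the 14-CpG marker — a deliberate ~140× reduction of a ~850k
array that preserves the feature structure the analysis uses.
`noise_sd = 0.5` M-units and `age_slope_sd = 0.0012` M-units/year were
calibrated together so that the default 96-man study yields a clock of the
accuracy scale reported for re-trained sperm clocks at this design
(r² ≈ 0.85–0.93, MAE ≈ 3–5 years in-sample), and so that the default
`bmi_acceleration_years = 1.4` — the observed high-BMI over-prediction
trend this design probes — stays statistically non-significant at 12 men
per cell, as in the study being emulated. Real aging effects in sperm
methylation are similarly subtle: per-CpG slopes of order 0.001–0.01
M-units/year.

### What the generator does not emulate

Probe-type chemistry, SWAN normalization, batch and position effects,
detection p-values, cell-type mixtures beyond the single somatic profile,
heteroscedastic per-CpG noise, and correlated residuals between neighboring
CpGs. Passing tests therefore demonstrate that the statistics behave
correctly under the stated model — unbiased slope recovery, controlled
family-wise error, calibrated null rejection — not that the pipeline is
robust to array artifacts it never sees.

## Preprocessing

- `beta_to_m` clips β to [eps, 1−eps] (default eps = 1e−6) and applies
  log2 β/(1−β); base 2 is the methylation-array convention.
- `qc_filter` drops probes by missingness only: the one QC criterion
  expressible on a β matrix (detection-p filtering needs raw intensities).
- `purity_screen` fails a sample when its mean marker β exceeds a
  threshold, default 0.5 — the midpoint of the sperm (≈0) and somatic (≈1)
  signatures. The pipeline excludes failing samples from all downstream
  analysis by default (configurable).
- `aggregate_regions` is the unweighted mean over member CpGs per sample,
  on whichever scale the caller passes in. Clock features default to
  β-scale region means in the pipeline (configurable to M). Note that the
  age effect is linear on the M scale, so M-scale features give a clock
  without the mild saturation bias that the inverse logit induces at the
  age extremes; the simulation suites that check quantitative recovery of
  an injected effect use M-scale features for exactly that reason.

## Differential methylation

Welch's two-sample t-test per unit on M-values — the standard choice for
group comparisons at n = 12 per group with no variance-equality
assumption. Units with fewer than two complete observations per group are
skipped and excluded from the family size. The Bonferroni family is all
tests of one level within one age category (point: all CpGs; regional: all
regions; global: one test), matching the within-category comparison
structure; adjusted p = min(1, p·m), significant at adjusted p < 0.05.
When both groups are constant and equal the test is reported as no
evidence of effect (statistic 0, p 1) rather than NaN.

## The clock

Objective, on standardized features X and response y:

    (1/2n)‖y − Xβ‖² + λ[α‖β‖₁ + (1−α)/2‖β‖₂²]

Cyclic coordinate descent with the soft-threshold update
β_j ← S(z_j, λα)/(1 + λ(1−α)), z_j = (1/n)Σ x_ij r_i^(−j). The update is
exact for standardized columns; the solver verifies the KKT conditions in
tests. Numerical choices:

- **Convergence** when the largest coefficient change in a sweep falls
  below `tol · SD(y)` (tol default 1e−7). The relative criterion matters:
  with ages in years the coefficients are O(10), and an absolute 1e−7
  cutoff sits at the float64 accumulation floor for the strongly
  correlated region features (all of which track the same latent age), so
  it would spin without terminating. Relative tolerance also makes the fit
  exactly equivariant under rescaling of the ages.
- **Response standardization.** `train_clock` and `cv_select_lambda`
  standardize y internally and rescale coefficients back to years (as
  glmnet does for gaussian fits). The ridge term is quadratic in β, so no
  single λ rescaling makes the elastic net scale-equivariant on a raw
  response; standardizing y makes λ dimensionless and the whole training
  procedure equivariant.
- **Path and CV.** λ grid: 100 log-spaced values from λ_max (the null
  threshold max_j |x_jᵀy|/n / max(α, 0.001)) down to λ_max·1e−4, warm
  starts descending. k-fold CV (default 10) restandardizes features and
  response inside each training fold, so no test-fold information leaks
  into the fit; selection rule is the CV minimum (1-SE rule available).
  α defaults to 0.5 and is exposed — an uncommitted midpoint between lasso
  and ridge, since nothing in the emulated design pins it.
- The mixing weight, penalty, standardization vectors, and coefficients
  are serialized as JSON, so a trained clock is portable and re-loadable
  bit-for-bit.

Training is on the full cohort, and the headline r²/MAE are in-sample — by
construction, mirroring re-trained-on-the-same-dataset reporting; the CV
machinery tunes λ only. A fixed dimensionless λ can be passed to skip CV,
which the simulation suites use for speed.

## GLAD and model comparison

GLAD = predicted/actual − 1 (scale-free; positive = epigenetically older).
Group comparison: Welch's two-tailed t-test of high- vs normal-BMI GLAD
within each age category, no correction across the four categories by
default (a Bonferroni flag exists). An injected acceleration of b years at
mean category age A yields an expected GLAD difference ≈ b/A — largest in
the youngest category — and the acceptance suite verifies quantitative
recovery of that pattern with a clock trained on an acceleration-free
cohort, since a clock trained on the accelerated cohort itself would
absorb part of b into its fit.

Two scalar r² values cannot be t-tested, so the model comparison is
operationalized as a paired two-tailed t-test on per-sample absolute
errors |e_with| vs |e_without|, with both models' r² and MAE reported
side by side. When cross-validation shrinks the BMI coefficient to exactly
zero the two clocks coincide and the comparison degenerates to statistic 0,
p = 1 — reported as such, not as an error. Which quantities the original
design's t-test actually compared is not recoverable; this reading is the
one coherent use of a paired t-test on these data and is recorded in the
report it produces.

## Simulation suite sizes

The acceptance suite runs its replicate studies at reduced scale, chosen
as the package's own desk-scale defaults: half-size cells (6 per cell, 48
men), a 12-region clock of 8 CpGs each with `age_slope_sd = 0.02` and
`noise_sd = 0.3` (a small array needs stronger per-region signal to carry
a usable clock), clocks fit at a fixed small penalty (λ = 0.01), and 500
replicates per study; the family-wise-error study uses one 12 v 12
category over a 200-CpG array. Tolerances are fixed a priori: recovery of
b/A within 3 replicate SEs plus a 5% attenuation allowance, null rejection
rates within 3 (cluster-robust) SEs of α = 0.05, and FWER at most
0.05 + 2.5 binomial SEs.

## Known limitations

- In-sample metrics overstate out-of-sample accuracy; the package reports
  them because the emulated design does, and the clock API makes held-out
  evaluation trivial (`predict_age` on any cohort).
- The BMI feature competes with 51 regions that already encode the
  accelerated epigenetic age; with an L1 component its coefficient is
  often exactly zero, so "with-BMI" and "without-BMI" clocks can coincide.
  When the coefficient is active under an injected acceleration it is
  negative — the clock subtracts the acceleration to recover chronological
  age — which is the correct direction for this design even though it may
  look counterintuitive.
- Bonferroni within level × category controls each family at 5%; across
  the 12 families of a full screen, an occasional single false positive is
  expected and visible in seeded runs.
- The generator's iid logit-normal noise makes region means unbiased and
  well-behaved; real arrays are messier (see the non-goals above), and no
  claim is made beyond the stated model.
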