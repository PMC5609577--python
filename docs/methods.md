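# Methods

## The calibration problem

Serum lipoproteins form a continuum of particle sizes. In a ¹H NMR
spectrum the lipid methyl (~0.6–1.04 ppm) and methylene (~1.04–1.4 ppm)
envelopes are superpositions of broad resonances, one pair per particle
class, whose chemical shifts increase with particle diameter. A
diffusion-edited acquisition suppresses small-molecule signals so these
lipoprotein envelopes dominate. Given a reference assay that reports TG
and CH concentrations per size fraction, a PLS-1 regression per
(class, lipid) can therefore deconvolve the envelope statistically. This
package implements that workflow; because no clinical data ship with it,
a forward simulator stands in for both the spectrometer and the
reference assay.

## Forward model of the spectra

Each of the 20 subclasses contributes two Lorentzian lines with centers

    methyl:    0.70 + 0.055 · ln(d / 9.8)   ppm
    methylene: 1.18 + 0.040 · ln(d / 9.8)   ppm

for diameter `d` in nm (half width 0.012 ppm). The logarithmic form
keeps all centers inside the 0.6–1.4 ppm feature window over the full
diameter range (7.9–95 nm) while preserving the monotone
size-to-shift ordering that makes the problem solvable; the constants
are free parameters of the simulator, not measured values. Line areas
are linear in concentration (1 area unit per mg/dL per species).
Cholesterol puts 85% of its area in the methyl line and 15% in
methylene; TG splits 40/60. This asymmetry is what makes the methyl-only
window sufficient for CH models while TG models need the full window —
mirroring how the real calibration windows are chosen. A synthetic
alanine doublet at 1.49/1.478 ppm (half width 0.004 ppm) lies outside
the feature windows and exists solely so the peak-alignment operation
has a target. Gaussian point noise (default SD 2.0, against methyl peak
heights of order 10²–10³) and an optional constant baseline complete the
model.

Registry diameters for the five subclasses outside the reference panel
(LDL12/13, HDL14/19/20) are log-linearly extrapolated from their
category neighbours and flagged `interpolated`; the largest chylomicron
fraction's censored bound (">90 nm") is stored as 95 nm and flagged.

## Cohort phenotypes

Concentrations are drawn from log-normal marginals (mean/CV
parameterisation — right-skewed and non-negative, which is also what
triggers the square-root transform rule downstream) coupled by a
Gaussian copula with correlation 0.5 between all outcomes of one
category. Two presets are shipped (`src/lipopls/presets.yaml`):

* `low_hdl_cm` — the low-HDL phenotype: substantial chylomicron and
  large-VLDL TG, depressed CH in the large HDL subclasses. Its means are
  the placebo marginal means of that phenotype converted from mmol/L to
  mg/dL; the five unmodeled edge subclasses get small means with CV
  0.08, reflecting that their models fail for lack of concentration
  range.
* `hyperchol` — a hypercholesterolemic comparison phenotype:
  chylomicrons essentially absent, lower large-VLDL lipids, higher CH in
  HDL15–17 and LDL08.

Only the qualitative contrasts between the presets are constrained by
the study the package emulates; the individual numbers are simulator
inputs, chosen once, not claims about any cohort.

What the simulator deliberately omits: full serum background (sugars,
amino acids, protein envelope), field/phase/baseline artifacts,
between-batch drift, non-Lorentzian line shapes, and any dependence of
line width on particle class. Passing tests therefore demonstrate that
the *pipeline* is correct and well calibrated under a faithful
signal-plus-noise model; they do not certify performance on real
spectra, where preprocessing quality and matrix effects dominate.

## Calibration engine

Per (class, lipid) the procedure is: extract the window (TG: 1746
points from the 1.4 ppm grid point upfield; CH: the last 961 of those),
decide the square-root transform (|sample skewness| > 1), split samples
80/42 by Kennard-Stone max-min selection on the TG-window features
(deterministic, ties to the lowest index), select the number of latent
variables by 10-fold cross-validation (seeded shuffled folds; smallest
count within 2% of the minimum CV-RMSE, search range 1–15), fit PLS-1
by NIPALS on mean-centered data, and run a response-permutation test:
the observed statistic is the cross-validated Q², each of B repetitions
permutes the response afresh over the same folds and component count,
and p = (#{null ≥ observed}+1)/(B+1). With B = 1000 and α = 0.001
(the defaults) a model is significant only if it beats every null.
Training metrics are computed from the 10-fold cross-validated
predictions, not refit residuals; test metrics from the held-out 42.
All metrics (Q² = 1 − PRESS/TSS, RMSE, CV% = 100·RMSE/mean, Pearson R)
are evaluated on the original mg/dL scale, squaring back
square-root-scale predictions with negatives clipped to zero (counted
on the model).

Numerical choices worth knowing:

* PLS-1 NIPALS needs no inner iteration for a single response and
  yields a nested component path; one deflation pass provides
  predictions for every truncation, which is what makes the
  CV-and-permutation loops affordable.
* Inside cross-validation and permutation loops, wide matrices
  (p > n) are first projected onto their row space via SVD. PLS
  predictions are exactly invariant under this projection (all
  coefficient vectors live in the row space), so results are identical
  to the full-space computation, about 20× faster for the 1746-point
  window. Stored models keep full-space coefficients.
* At full rank PLS-1 reproduces the least-squares fit; this and the
  equivalence to scikit-learn's PLS are cross-checked in the tests, not
  used in the implementation.
* The permutation p uses the add-one estimator, so the smallest
  attainable p is 1/(B+1); runs with reduced B (the analysis drivers
  use 199) cannot reach α = 0.001 and report accordingly.
* Predictions outside a model's training concentration range are
  flagged, since calibration validity is only claimed within that range.

PCA screening uses a deterministic sign convention (largest-magnitude
loading element positive). Representative-sample selection partitions
the PC1 score range into equal-width bins, takes the nearest unselected
sample per bin center and always includes both extremes. Outlier
screening computes Hotelling T² on the first two components against the
F-based 99% control limit and escalates to whole-subject exclusion when
a majority of a subject's samples are flagged.

## Cross-cohort bias

A panel trained on one phenotype is applied to the other cohort's
held-out spectra and compared with the matched-cohort panel. Bias is
summarized per (class, lipid) as the mean signed error in mg/dL (the
scale on which zero-concentration classes remain well defined), the
slope/intercept of the predicted-vs-observed line, and the fraction of
out-of-range predictions. The mechanism the experiment reproduces: the
chylomicron-naïve panel has no coefficients to absorb CM/large-VLDL
intensity, so that intensity leaks into every prediction through the
PLS coefficient vectors, inflating errors even where correlations stay
high. No correction or calibration transfer is attempted — the
diagnosis is the product.

## Crossover treatment analysis

The trial generator produces a balanced two-period crossover (even
subject count, half per sequence) with sampling at each period start
(D1/D57, pre-treatment baselines) and twice in the final treatment week
(D25/D28, D81/D84). Outcomes are multiplicative: subject trait level ×
treatment multiplier × exp(subject effect) × exp(visit noise), with
log-scale SDs defaulting to 0.15 (subject) and 0.05 (visit).

Each (class, lipid) outcome is analyzed with a linear mixed model on
post-treatment observations: fixed effects treatment, same-period
baseline value (continuous ANCOVA covariate), gender, age, BMI and
visit; a random intercept per subject; REML. Two interpretive choices:

* "Baseline" enters as the subject's same-period pre-treatment value,
  not as a day factor — the reading under which LSMeans are "corrected
  for baseline".
* In addition to the subject intercept, a subject-period variance
  component is included. Both visits of a period regress on the *same*
  baseline measurement, so their residuals share that measurement's
  error; with only a subject intercept this period-level correlation
  deflates the treatment SE (null simulations showed a Wald z with SD
  1.27 and a 12.5% type-I rate at α = 0.05). With the component the
  test is calibrated (z-SD 1.04, 4% empirical rate), as the null-
  calibration test verifies.

LSMeans are model predictions at the means of the continuous covariates
and balanced (0.5) margins of the categorical ones; the treatment
effect is reported as 100·(active − placebo)/placebo to two decimals
with a Wald p-value. With two arms the Dunnett-Hsu multiplicity
adjustment is the identity and is kept as an explicit labeled
pass-through (a conservative Šidák-type bound is applied for more
arms). Outcomes are analyzed untransformed and no adjustment is made
across the (class × lipid) outcomes, matching per-outcome reporting at
p < 0.05. If the REML fit fails, the model falls back to subject fixed
effects with a warning (between-subject covariates are then absorbed).

## Problem sizes and defaults

Cohorts default to n = 122 with an 80/42 split; the crossover to 40
subjects. The analysis drivers run the permutation tests at B = 199
(with α relabeled 0.01 accordingly) and the test suite uses smaller
B and cohort sizes per test; the package default remains B = 1000,
α = 0.001. All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning, and rerunning any driver or the
pipeline with the same seed is byte-identical.

## Known limitations

* The simulator's concentration-to-spectrum map is exactly linear and
  shared across samples; real spectra violate this (line-width and
  shift variation with temperature, lipemia, protein background), so
  real-data Q² values will be lower and more heterogeneous.
* Permutation tests assume exchangeability of samples; the simulated
  cohorts are i.i.d., real cohorts with repeated subjects are not.
* Mixed-model p-values are Wald (normal) rather than
  Kenward-Roger-adjusted; at 40 subjects the difference is small, and
  the null-calibration test bounds it empirically.
* The Dunnett-Hsu generalisation beyond two arms is a conservative
  bound, not the exact multivariate-t quantile.
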