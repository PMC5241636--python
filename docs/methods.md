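# Methods

## The chaining framework

One single-output model per time point, fitted in time order (the chain
order equals the order of the sampling grid). The first target is always
modelled from the herb proportions alone. For target *j* ≥ 2:

* **ST** — features ⟨x₁, x₂, x₃⟩ only;
* **MT** — features plus the chain's prediction of target *j−1*
  (optionally the last *k* predictions, `n_augment=k`; *k* = 1 is the
  default because longer augmentations performed worse in the original
  study and in our synthetic experiments they add variance without
  information);
* **RMT** — features plus the prediction of one other target drawn
  uniformly from the remaining eight, one draw per position, from a seeded
  generator; a draw may point *forward* in the chain, in which case the
  augmentation value comes from an auxiliary single-target model of that
  time point fitted on the features alone (the chain's own prediction of a
  later target does not exist yet when an earlier one is predicted).

Augmentation uses predictions everywhere: the in-sample predictions of the
already fitted part of the chain during training, and the chain's
predictions on the new samples at prediction time. Measured target values
are never used — they are unknown for new samples by definition, and using
them in cross-validation would leak the targets. A study flag
(`use_true_targets=True`) switches the *training-time* augmentation to
measured values for comparison; it is off by default and not used in any
reported result.

### A consequence worth knowing

With prediction-based augmentation, every augmented column is an exact
function of the features. For an unregularised linear base (LR, or PR of
degree 1) the augmented column is an exact *linear* function of X, so the
least-squares fit spans the same space with or without it: **the MT chain
is prediction-identical to ST for the LR base** (differences are at
floating-point level). Genuine differences arise for scale-sensitive or
nonlinear learners — SVR (the augmented, strongly predictive feature
changes the regularised geometry), PR degree ≥ 2 (squares of the augmented
feature are new functions), ANN and PLSR. Accordingly, comparisons that
assert "MT ≤ ST" treat numerically equal errors (within a 1e-9 relative
band) as ties satisfying ≤.

## Error measures and reports

Per-target over the *l* pooled held-out predictions:
RMSE_j = √(Σᵢ(ŷᵢⱼ−yᵢⱼ)²/l), MAE_j = Σᵢ|ŷᵢⱼ−yᵢⱼ|/l,
MAPE_j = Σᵢ|ŷᵢⱼ−yᵢⱼ|/|yᵢⱼ|/l (fractional scale, so 0.2 means 20%).
The whole value of a measure is the mean of its per-target values; the
accompanying dispersion is the sample SD (n−1) across the nine targets.
(Across-fold SD would be the other defensible reading; across-target is
what one value ± SD per table cell implies, and is what we implement.)

MAPE is undefined when a true value is zero; the package raises rather
than inserting an epsilon. Evaluation entry points default to
`include_mape="auto"`: MAPE appears only for datasets whose true values are
all nonzero. On the default synthetic suite MAPE is therefore absent — the
10-min absorption lag zeroes the 5-min point, and zero-dose single-herb
prescriptions give all-zero curves.

LOOCV refits the chain m times on m−1 samples; under RMT the augmentation
plan is redrawn per fold from `seed + fold_index` (reproducible, but the
randomness varies across folds as a random-target comparison should).
Improvement percentages: imp = (err_ref − err_new)/err_ref × 100.
Report CSVs round RMSE/MAE and improvements to two decimals and MAPE to
three, matching the precision of the published tables.

## Base learners

| learner | implementation | defaults and rationale |
|---|---|---|
| LR | numpy SVD least squares (minimum-norm) | pseudo-inverse handling tolerates the rank deficiency of the orthogonal design and collinear augmented columns |
| PR | polynomial features (total degree ≤ 2, with interactions) + least squares | "max order 2" read as total degree |
| SVR | scikit-learn SVR | linear kernel, C = 1.0, ε = 0.1; features z-scored on the training fold only (proportions ~1 vs augmented concentrations ~100s) |
| ANN | scikit-learn MLPRegressor | one hidden layer of 8 units, L-BFGS, seeded init, max-iteration cap with convergence warnings surfaced |
| PLSR | scikit-learn PLSRegression | min(p, 3) components, overridable |

All fits are deterministic given (spec, data, seed). Whether the original
study standardized inputs for SVR/ANN is unknowable from the published
text; internal standardization is our default and is exposed as a flag.

## The synthetic generator

The generator emulates the study conditions: 12 compatibility groups × 3
replicates = 36 samples per compound, five compounds dosed from the printed
extract mass fractions (ber 23.03% and pal 5.52% of coptis extract, evo
0.38% and rut 0.48% of evodia, pae 13.41% of peony). Which 12 of the 18
printed prescriptions entered the original experiment is not recorded; the
default takes the nine orthogonal combinations plus the middle-dose
single-herb prescription of each herb (11#, 14#, 17#), overridable.

Curves follow a one-compartment oral model with lag,
C(t) = (D/(V/F))·ka/(ka−ke)·(e^{−ke(t−tlag)} − e^{−ka(t−tlag)}), the
minimal mechanism with the observed rise–peak–decline shape and a full set
of non-compartmental indices. Defaults: ka = 0.05/min, ke = 0.008/min,
tlag = 10 min, V/F = 1, unit dose 1000 per unit herb amount — chosen so the
peak falls inside the 5–480 min grid (≈ 55 min) and concentrations land in
the hundreds, the magnitude of the published error tables. Compatibility
enters twice: dose is linear in the source-herb amount, and the other two
herbs perturb ka and ke log-linearly (defaults +0.20/−0.15 per unit
amount); a perturbation that would drive ka ≤ ke is clipped to 1.05·ke with
a warning.

Stochastic structure: a per-sample lognormal random effect on dose
(CV 10%, mean 1) scales each whole curve, creating the across-time-point
correlation that chaining exploits; point-wise multiplicative lognormal
assay noise (CV 15%, mean 1) sits on top. Everything is driven by seeded
generators.

What the generator does **not** emulate: correlations between compounds
sharing a source herb (compounds are simulated independently),
between-subject kinetic variability beyond the dose effect, non-linear
(saturable) kinetics, assay quantification limits, and the unknown true
composition–kinetics relationship. Passing tests therefore demonstrate the
framework's behaviour under its assumed correlation structure, not
agreement with the original in-vivo error magnitudes — those are not
reproducible without the unpublished measurements, which is why the
published improvement *arithmetic* (not the absolute errors) is the
external anchor.

## Non-compartmental analysis

Cmax/Tmax from the sample maximum (earliest time on ties); Tlag is the last
sampling time still at zero before the first positive value (0 if the first
sample is positive); AUClast by linear trapezoid (log-down variants are a
known alternative; linear is the simplest defensible default for sparse
grids); Lambda_z as minus the slope of the least-squares line of
ln C vs t over the terminal points — by default the last three positive
points strictly after Tmax, optionally the suffix (≥ 3 points) maximising
adjusted R². AUCINF_obs = AUClast + C_last/Lambda_z;
Vz_F_obs = dose/(Lambda_z·AUCINF_obs) and Cl_F_obs = Vz_F_obs·Lambda_z,
computed in that order so the volume–clearance identity holds exactly in
floating point. Fewer than three usable terminal points ⇒ Lambda_z and its
dependants are NaN with a `lambda_defined=False` flag, never silent zeros.

## Problem sizes and reproducibility

The chain-benefit statistics use 20 seeded replicates of the full
five-compound suite (36-sample LOOCV each) — about a minute of compute —
which puts a standard error of a few percentage points on the win rate.
Every CLI run writes a manifest (normalised config + seed + version) from
which the outputs rebuild byte-identically; all randomness flows through
`numpy.random.default_rng` seeds derived from the user seed.

## Known limitations

* Table 1 dose units are unspecified in the available text; values are
  treated as dimensionless levels.
* The published SD semantics and the whole-error formulas are interpreted
  (mean and SD across targets), as is test-time augmentation (predicted,
  not measured, previous targets); both interpretations are documented
  above and flagged as such.
* Chain order is fixed to time order; alternative orders and
  ensemble-of-chains averaging are out of scope.
* NCA settings of the original study are unknown; exact numeric agreement
  with its (unpublished) index values is not claimed.
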