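# Methods

## The problem and the model

Ultrasound examination of a thyroid nodule yields a dozen categorical
findings (irregular margin, unclear border, hackly border, halo,
micro/macro-calcifications, solid vs mixed component, taller-than-wide
shape AP/T ≥ 1, blood-flow pattern, vascularity, posterior attenuation,
lateral shadow, hypo- vs hyper-echogenicity) plus continuous measurements
(nodule size, patient age, echogenicity ratio).  No single finding reliably
separates malignant from benign nodules; the package combines them into a
per-nodule malignancy *risk score* and a four-level management category,
treating the surgical diagnosis as the gold standard.

The pipeline has four stages.

**1. Per-characteristic diagnostics.**  Each level of each characteristic
is assessed one-vs-rest: a nodule is "positive" when it shows exactly that
level, all other levels pooling into "negative".  From the 2×2 table,
SEN = TP/(TP+FN), SPE = TN/(TN+FP), PPV, NPV, and the dichotomous-predictor
AUC = (SEN+SPE)/2, which provably equals the rank (Mann–Whitney) AUC of the
0/1 indicator.  Association is tested with the two-sided Fisher exact test
(probability-ordering rule); continuous measurements with the tie-corrected
Mann–Whitney normal approximation.  Percentages are reported at one
decimal, AUCs at three, mirroring clinical reporting practice.

**2. Echogenicity-ratio cutoff.**  The echogenicity ratio ER (nodule
echogenicity / anterior-cervical-muscle echogenicity) is dichotomized as
hypoechoic iff ER ≤ c.  The cutoff scan evaluates the hypoechoic
indicator's AUC at every observed ER value in [0, 5] (a fixed-step grid is
available by flag) and keeps the AUC-maximizing cutoff, ties resolving to
the smaller — more sensitive — cutoff.

**3. Characteristic selection.**  Logistic regression of malignancy on the
dummy-coded characteristics with an L1 penalty:

    maximize  (1/n) Σᵢ [ yᵢ ηᵢ − log(1 + exp(ηᵢ)) ]  −  λ Σⱼ |βⱼ|,
    ηᵢ = β₀ + xᵢᵀβ,

with an unpenalized intercept and covariates standardized to unit variance
internally (the penalty acts on the standardized scale; coefficients are
returned on the original scale).  The objective is averaged over records,
so λ_max = maxⱼ |Σᵢ x̃ᵢⱼ(yᵢ − ȳ)|/n is the smallest penalty with all-zero
slopes; a penalty on the summed log-likelihood is the same problem with
λ scaled by n.  λ is chosen by 10-fold outcome-stratified cross-validation
of the held-out binomial deviance over a 100-point log-spaced grid spanning
[0.01·λ_max, λ_max], taking **lambda.1se** — the largest λ whose CV
deviance is within one standard error of the minimum.  The whole procedure
(stratified 60/20/20 split → CV on the training split → refit at
lambda.1se → record characteristics with any nonzero coefficient, grouping
a categorical characteristic's level indicators) is repeated over R random
splits; characteristics selected in at least half the repetitions (the
configurable retention threshold) are retained.

The solver is a proximal-Newton coordinate descent (IRLS outer loop,
cyclic soft-thresholding inner loop, active-set sweeps, warm starts along
the λ path).  Every returned solution is certified against the subgradient
optimality conditions: |gⱼ| ≤ λ + tol where βⱼ = 0 and
|gⱼ − λ·sign(βⱼ)| ≤ tol otherwise, with g the standardized-scale gradient.
At λ = 0 the fit agrees with an independent Newton maximum-likelihood
oracle to 1e-6; at moderate λ the achieved objective agrees with a
bound-constrained L-BFGS-B oracle to 1e-8.

**4. Scoring and stratification.**  A classifier (default: random forest,
500 trees, 2 candidate features per split, class probability = fraction of
trees voting malignant) is trained on the training part of each of R fresh
stratified splits, restricted to the retained characteristics, and emits a
probability for every nodule.  A nodule's risk score S is its probability
averaged over repetitions.  Performance per repetition uses the
closest-to-(0,1) ROC threshold derived on that repetition's validation
split and is averaged over repetitions (AUC, SEN, benign-class F1, SPE,
PPV, NPV).  F1 is computed on the **benign** class — precision = NPV,
recall = SPE, F1 = 2·NPV·SPE/(NPV+SPE) — which is the only convention that
reproduces the benchmark tables' F1 cells from their own SPE/NPV columns.

Scores are then cut into four categories at three boundaries
(left-closed):

* **l_c** — the 2.5th percentile of 1000 bootstrap resample means of the
  *benign* nodules' scores on the train+validate set (the lower end of the
  standard 95% percentile interval).  A cohort-wide mean is implausible as
  a lower boundary at 83% prevalence (it sits far above 0.5), so the
  benign-only pool is the default, with a flag to override.
* **0.5** — the conventional class-probability midpoint.
* **h_c** — the closest-to-(0,1) ROC threshold of the train+validate
  scores.

Thresholds are derived on a frozen reference train+validate split and then
applied unchanged to the held-back test split.  Categories carry fixed
management strings (6-month follow-up / 3-month follow-up or FNA / FNA /
FNA or surgery).

### Scoring mode

`ensemble_risk_scores` offers two averaging modes.  `all_predictions`
averages every repetition's probability for every nodule, including
repetitions where the nodule was inside the training split.  For a random
forest queried on its own training data those in-bag vote fractions are
nearly 0/1, which pushes every malignant nodule's score above ~0.46 and
empties the lower risk categories of malignant nodules.  `out_of_split`
averages only repetitions in which the nodule was *not* used for training;
these honest probabilities span the full range (minimum malignant scores
near 0.1–0.15) and produce the expected monotone malignancy gradient
across the four categories, so it is the model-level default.  (R's
`randomForest` quietly returns out-of-bag votes when `predict` is called
without new data, which is consistent with the published score
distributions.)  `out_of_split` requires each nodule to be held out at
least once and therefore rejects very small repetition counts
(P(never held out) = 0.6^R per nodule).

## The synthetic cohort generator

The study cohort (1448 surgically confirmed nodules, 1200 malignant / 248
benign) is not publicly deposited, so a calibrated generator stands in for
it:

* outcome ~ Bernoulli(1200/1448);
* each categorical characteristic drawn independently given the outcome,
  with P(level | outcome) equal to the published class-conditional count
  ratios; the reference level of each characteristic is derived from the
  config as the level with the lowest implied malignancy rate;
* ER | class ~ log-normal with log-SD σ = 0.5 (a free shape knob) and
  log-location pinned by P(ER ≤ 1.3 | malignant) = 0.767 and
  P(ER ≤ 1.3 | benign) = 0.472; echogenicity is *derived* by thresholding
  the simulated ER at 1.3, keeping the categorical marginal and the
  continuous calibration consistent by construction;
* age | class ~ normal (benign 57.2 ± 10.7, malignant 43.1 ± 11.4 years)
  truncated to the cohort's observed range [10, 80];
* size ~ log-normal in mm, median 10 (benign) vs 12.5 (malignant),
  log-SD 0.6 — an invention (no size distribution was published), with the
  class difference included because the cohort's rank test found size
  significantly associated with malignancy;
* sex is cosmetic (P(female) = 0.79 in both classes) and about 5% of
  nodules share a patient id, mirroring the 1448-nodule / 1370-patient
  ratio.

An `abnormal` preset swaps the class-conditional frequencies of the strong
visual signs (shape, margin, hackly border, component, calcification) and
inverts the ER model at 10% prevalence, emulating the study's adversarial
"abnormal nodule" subgroup.

**What the generator does not emulate:** dependence among characteristics
(only marginals are published, so levels are conditionally independent
given the outcome — real findings co-occur), the true ER and size
distributions beyond the printed calibration points, reader variability,
and patient-level clustering beyond shared ids.  Because the conditionally
independent features carry more joint information than correlated real
ones, classifiers separate the synthetic classes more cleanly than the
published benchmarks (test AUC ≈ 0.98 vs 0.958); passing tests demonstrate
that the machinery is correct and the qualitative structure (selection
frequencies, monotone category gradient) is reproduced, not that real-data
performance would match.

## Numerical choices

* Penalized-likelihood convergence: IRLS stops when the working linear
  predictor changes by < 1e-9 (1e-7 inside the CV path for speed); IRLS
  weights floored at 1e-8; predicted CV probabilities clipped to
  [1e-9, 1 − 1e-9] before the deviance.
* "Nonzero coefficient" means |β| > 1e-10.
* Largest-remainder rounding allocates split sizes within each outcome
  stratum (deviation from the target proportions ≤ 1 record); ties in the
  fractional parts resolve in train/validate/test order.
* Cutoff candidates are midpoints of adjacent sorted unique scores plus
  ±∞; predicted-malignant uses strict `>`; ties in the ROC distance
  resolve to the smallest threshold.
* PPV/NPV (and hence benign-class F1) are reported absent, not 0, when a
  predicted class is empty; repetition averages skip absent values and
  report the contributing count.
* All randomness flows from one master seed through per-stage derived
  seeds (recorded in the results provenance); identical seeds give
  byte-identical outputs.
* Missing values are rejected at I/O, never imputed.  Nodule size is
  recorded in millimetres.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the study-scale cohort
(n = 1448) but fewer repetitions than the study's 100 — 50 repeated splits
for the selection-frequency check, 8–20 for selection and 20 for scoring in
the end-to-end runs, and n = 5000 for generator-calibration and ER-scan
checks.  These sizes keep a full run on a single CPU in the minutes range
while leaving every Monte-Carlo tolerance at 3–4 standard errors of the
quantity checked.

## Known limitations

* Class-conditional independence makes the synthetic problem easier than
  the real one (see above); selection frequencies of weak characteristics
  (halo, attenuation, blood flow) are therefore seed-sensitive.
* The exact published thresholds (l_c = 0.265, h_c = 0.784) and category
  rates are not reproducible without the raw data; only their qualitative
  structure is.
* Comparison classifiers beyond the random forest and the logistic model
  are thin adapters around scikit-learn estimators with approximately
  mapped hyperparameters; they satisfy the backend contract but are not
  tuned replicas of the R implementations they mirror.
* The Mann–Whitney p-value uses the asymptotic normal approximation; exact
  small-sample p-values are out of scope.
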