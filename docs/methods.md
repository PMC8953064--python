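# Methods

## Measurement model

Responses are modelled on a single logit scale. A dichotomous item i has
success probability `logistic(theta_n - b_i)`; a polytomous item follows the
Partial Credit Model (PCM), `P(x=k) ∝ exp(sum_{j<=k}(theta_n - b_i -
tau_ij))` with `tau_i0 = 0`. The item location `b_i` is the mean of the
item's absolute step difficulties and the thresholds `tau_ij` are centred to
sum to zero, so dichotomous and partial-credit items share one difficulty
metric. A PCM item with one step and `tau = 0` is exactly the dichotomous
model, which the tests assert.

## Estimation

Joint maximum likelihood (JMLE): persons and item steps are updated by
alternating one-parameter Newton–Raphson sweeps, each update damped to ±1
logit. The joint log-likelihood is concave, so the alternating scheme
converges to the joint maximiser; the acceptance suite verifies agreement
with an exhaustive profile-likelihood grid search (refined below 0.002
logit) on every estimable complete dichotomous matrix up to 5 × 4,
enumerated through its sufficient margins. Identification is by mean item
difficulty 0; at each sweep the common shift is moved into the person
measures, leaving the likelihood unchanged.

Details and conventions:

* **Convergence**: largest absolute parameter change < 1e-4 logits
  (default), 200-sweep budget; non-convergence returns partial results with
  `converged=False` rather than raising.
* **Extreme scores**: persons and items with zero or perfect observed
  totals, persons with fewer than two administered items, and items without
  two distinct observed categories are removed iteratively before
  estimation (they carry no information about their own parameter). Their
  ids are reported; their measures are NaN. Score-to-measure rows for the
  extreme raw scores are extrapolated by pulling the score inward by 0.3
  score points, the conventional adjustment.
* **Missing responses** are "not administered": skipped in every likelihood,
  expectation, fit and reliability sum; never imputed.
* **Standard errors** are inverse square roots of the observed information:
  `1/sqrt(sum_i W_ni)` for persons and `1/sqrt(sum_n W_ni)` for item
  locations, where `W` is the model score variance of the cell.
* **Bias**: JMLE difficulty estimates are inflated outward by roughly
  k/(k−1) at k items. Estimation is uncorrected by default; an optional
  `(k−1)/k` shrinkage flag (`EstimationSettings.bias_correction`) implements
  the standard correction, and the parameter-recovery study is assessed on
  the corrected estimates, the conventional estimator for recovery work.
* Some complete matrices with interior margins still have no finite joint
  MLE (the item comparison digraph is not strongly connected — quasi-
  separable data). These cannot converge; the oracle test excludes them by
  that graph criterion and the estimator flags them via `converged=False`.

## Fit statistics

Standardized residual `z = (x − E)/sqrt(W)`. Outfit mean-square is the
unweighted mean of `z²`; infit is `sum(W z²)/sum(W)`. Standardized values
use the Wilson–Hilferty cube-root transform with the exact sampling variance
of each mean-square (fourth central moments of the cell distributions).
Point-measure correlation is the Pearson correlation of item scores with
person measures. Persons without finite measures are excluded from all fit
sums.

Mean-squares in [0.5, 1.5] are treated as productive; an item becomes an
outfit removal candidate only when outfit mean-square > 1.5 **and**
standardized outfit > 2. Items with mean-squares below 0.5 are noted, never
removed (overfit is unproductive, not degrading).

## Assumption screens

* **Unidimensionality**: largest eigenvalue of the Pearson correlation
  matrix of item standardized residuals (pairwise-complete), reported in
  item units; < 2 items-worth passes. Correlations rather than covariances,
  matching the "items-worth" rule of thumb.
* **Local independence**: largest |pairwise residual correlation| < 0.50,
  with both signed extremes reported.
* **Monotonicity**: the test characteristic curve (sum of expected item
  scores) sampled on 201 points over [−6, 6] must be strictly increasing —
  analytically guaranteed for these models, so the check guards
  implementation defects.

## Purification

One item per round: calibrate, diagnose, remove the single worst candidate,
repeat until no candidates remain; assumption screens rerun each round; the
full trace (trigger, value, fit and assumption snapshots) is recorded.
Candidates are ordered worst outfit mean-square first (ties: larger |ZSTD|,
then item id); items with negative point-measure correlation are polarity
candidates appended after the outfit list **and are never classified as
outfit candidates** — residual fit statistics presuppose correct keying, so
polarity is screened first, the standard practice. A keep-list provides the
theory-driven override for retaining an item regardless of fit. Purification
below 3 items raises rather than continuing.

Person misfit is handled once after the item set stabilizes: persons with
outfit mean-square > 2.0 are removed in a single round; the reduced dataset
is adopted only if item fit improves — a strict decrease in the count of
items with outfit outside [0.5, 1.5], with mean |outfit ZSTD| as the
tie-break — and never when fewer than 30 persons would remain. The 2.0
cutoff is a documented convention; the threshold is configurable.

## Uniform DIF

Anchored two-stage design: person measures come from the pooled calibration;
holding them (and PCM threshold spacing) fixed, each item's location is
re-estimated by a one-dimensional Newton step within each group. The
contrast between group difficulties is tested with a Welch-style t
(Satterthwaite degrees of freedom from the two anchored SEs); an item is
flagged only when |contrast| ≥ 0.5 logits and p < 0.01 — the joint rule is
the multiplicity control; no additional FDR layer is added. Groups below
100 persons draw a warning (0.5-logit DIF is then unreliable to detect).
Age is banded 12–15 vs 16–18 for screening. Only uniform (constant-shift)
DIF is modelled. A Mantel–Haenszel common odds ratio stratified on raw
total score is provided for dichotomous items as a corroborating statistic,
not a flag source. Under the null the anchored t statistics are
approximately standard normal (KS-checked); empirical null flag rate is
≤ 2% and power for a 1-logit shift at ~300/group is ≥ 90%.

## Reliability and strata

* **Item separation reliability**: (population variance of difficulties −
  mean squared SE) / variance, floored at 0. The person analogue is
  computed but secondary — for ability-skewed samples the sample-independent
  statistic below replaces it.
* **KR-20 / coefficient alpha**: `(k/(k−1))(1 − Σ var_i / var_total)` on
  complete cases with population variances; for dichotomous items the item
  variance is p·q, giving the classical KR-20 exactly (cross-checked
  against an independent alpha implementation).
* **Wright strata**: raw-score SEs from the score-to-measure table are
  inflated by 10%; walking up from the lowest attainable score, a new
  performance level opens at the first score whose measure exceeds the
  current level anchor's by at least `2·sqrt(SE_infl(anchor)² +
  SE_infl(s)²)`, and the anchor resets there. The comparison is always
  against the level's first (lowest) score, and the inflated SEs enter at
  both endpoints — the two points where the procedure's phrasing is open,
  both documented here. Sample-independent reliability is `n²/(1+n²)`
  (2 levels → 0.80, 4 levels → 0.94). Published cutoff presets for the
  four assessments (and the younger-group composite variant) ship as a
  versioned JSON resource.

## Validity battery

NVS-style screener: six dichotomous items summed 0–6 and banded 0–1 / 2–3 /
≥4 (missing responses count as incorrect, with a warning). Convergent
validity is a pairwise-complete Pearson correlation. Criterion validity is
a logistic regression of a binary behavior on the raw score with additive
demographic covariates (gender as a binary indicator, age in years
continuous, ethnicity as a binary indicator — a documented coding choice),
reporting the per-point odds ratio with Wald 95% CI; complete separation is
detected and flagged. Discrimination is the Mann–Whitney AUC with tie
correction, converted to Cohen's d by the equal-variance binormal relation
`d = √2 · Φ⁻¹(AUC)` — the closed form generating the published conversion
tables; a table-snap mode rounds to 2 decimals to mimic lookup.

## Synthetic cohorts

The generator emulates the motivating study design: 355 persons answering a
23-item battery — 6 + 10 + 2 dichotomous and 5 partial-credit items whose
score ceilings (2,2,2,3,3) give a 0–14 critical sub-scale and a 0–30
composite. Default true difficulties span −2.05…2.91 logits. Person
ability is a two-component normal mixture, 0.9·N(1.9, 0.95) + 0.1·N(0.5,
2.0), calibrated once by moment-matching against the reported cohort
observables (composite mean ≈ 23.9, SD ≈ 5.0, negative skew ≈ −0.8, and an
item-SE profile spanning ≈ 0.10–0.29); a mixture rather than a skew-normal
keeps the parameterization transparent. The NVS-like convergent measure
adds N(0, 1) noise to ability before six pseudo-items at difficulties
1.3–3.6, reproducing a ~0.45 convergent correlation and a realistic
screener category mix. Criterion behaviors are Bernoulli draws from a
logistic link on the summed score (default slope log(1.15) per composite
point).

Injections with recorded truth: uniform DIF shifts keyed to covariate
levels; misfitting persons (full random responders or careless tails);
noise items — flat success-rate items independent of ability (default rate
0.25; the purification studies use 0.15–0.2, the guessing-style archetype
of a misfitting item; a 0.5-coin is nearly undetectable by outfit in a
homogeneous sample because it mimics a well-fitting item at the sample
centre); and reverse-keyed items with configurable negative slope (the
polarity-failure archetype is a fully flipped easy item). The truth record
suffices to recompute every generating probability, which the tests assert.

What the generator does **not** emulate: classroom clustering, item-content
effects, response styles beyond the two misfit mechanisms, non-uniform DIF,
and missingness that depends on ability (missing cells are MCAR). Passing
recovery tests therefore show the pipeline's statistical machinery is
correct under its own model, not that any real instrument is valid.

## Problem sizes in the test suite

The simulation suites run at the design's natural sizes: 20 replicates of
the 355 × 23 recovery study; 20 replicates each of the 12-item (6 noise)
and 15-item (4 noise + 1 reversed) purification studies; 100 replicates
each for DIF null and power at ~300/group; 5 model-consistent 500 × 20
cohorts for null fit behaviour. The oracle comparison covers all 147
estimable margin configurations up to 5 × 4 (143 with finite MLEs).

## Known limitations

* JMLE's outward bias is inherent; only the optional multiplicative
  correction is provided (no CMLE/MMLE).
* Person outfit at 20-item test length is noisy (≈ chi²₂₀/20 under the
  model), so a single injected random responder lands in the worst decile
  of the cohort rather than reliably ranking first; detection statements
  about persons are therefore decile-based.
* The first-contrast screen uses the residual correlation PCA directly;
  bootstrap or exact null distributions for fit statistics are out of
  scope.
* DIF contrasts from short tests inherit person-measurement error and can
  overshoot at small n; the flag rule's joint magnitude+significance gate
  absorbs this in practice.
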