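# Methods

## The decision problem and the gold standard

Each patient has two candidate irradiation positions.  The package's unit
of truth is the LAD mean dose difference Δ = D̄(supine) − D̄(prone) in Gy;
the binary gold-standard label is 1 ("supine preferred") when Δ < 0 and 0
("prone preferred") when Δ > 0.  An exact tie Δ = 0 is labelled 0: ties
have probability zero under the continuous generator, and a deterministic
rule keeps every pipeline stage reproducible.  All classifier positives are
"supine" calls, and every thresholding rule in the package is closed on the
positive side (`score ≥ t` calls positive) — one convention, used
identically in ROC analysis and net-benefit computation.

## Candidate models

* **Univariate logistic** per predictor (BMI, A_heart, d_median, PTV):
  maximum-likelihood fits of the label; they serve both as baselines and as
  the probability constructions behind per-predictor Brier scores.
* **Main-effect logistic**: `a_heart + bmi + d_median`.
* **Interaction logistic**: intercept plus exactly `a_heart·bmi` and
  `a_heart·d_median`, no main effects.
* **Stepwise logistic** over a user-supplied candidate set, selected by
  likelihood-ratio χ² tests: forward enters the smallest-p candidate while
  p < `p_enter` (default 0.05), backward removes the largest-p term while
  p > `p_remove` (default 0.10) — the defaults of the major commercial
  implementations of these procedures.  A non-convergent step is skipped
  and logged, never fatal.  Note the family-wise consequence of per-term
  testing: with k pure-noise co-candidates, forward selection terminates
  with *only* the true predictor at rate ≈ (1 − p_enter)^k (≈ 0.86 for
  k = 3), so occasional extra noise terms are expected behaviour, not a
  defect.
* **Linear dose model**: OLS of Δ on `a_heart + bmi + d_median`.  Its
  decision is the sign of the predicted difference (positive → prone); an
  exact zero prediction falls to prone, mirroring the label tie rule.  Its
  advantage over the logistic family is quantitative: it predicts *how
  much* dose is at stake, not only which side of zero the patient is on.

**Separation handling.**  Complete or quasi-complete separation makes the
logistic MLE diverge.  Instead of failing (fatal inside resampling loops),
the fit is re-run on the standardized design with slopes box-constrained to
|b| ≤ 15 by L-BFGS-B and flagged `separation=True`.  A standardized slope
of 15 is far beyond any probability resolution that matters (odds ratios of
e¹⁵ per SD), so the cap changes nothing numerically except existence.
Standard errors are not reported for capped fits.

**Predictor clustering.**  Agglomerative clustering with distance
1 − |Pearson r| and average linkage.  The absolute value targets
multicollinearity regardless of sign; the full merge history is returned so
an analyst can pick poorly correlated predictor subsets rather than being
handed a fixed partition.

## Performance metrics

Confusion-based measures use the standard definitions; any measure with an
empty denominator is NaN ("not available"), never silently zero.  The AUC
is the tie-corrected Mann–Whitney statistic computed from midranks —
concordant pairs plus half-ties over all positive–negative pairs — and its
95% CI uses DeLong's structural-components variance.  The Youden-optimal
cut-point scans midpoints between adjacent distinct scores plus ±∞
sentinels (every achievable confusion table appears exactly once); Youden
ties break toward the higher-specificity cut.  Brier scores are computed
against the probability of class 1 (supine); the weighted form divides by
the weight sum, so equal weights reproduce the unweighted score exactly.
Weights are a user input (|Δ| is the natural choice when dose magnitudes
should matter); no particular weighting is baked in.

## Net benefit and decision curves

With profit p per true positive and loss l per false positive, Peirce's
utility is B = (p·TP − l·FP)/N.  Since p and l are unmeasurable in this
setting, the loss-to-profit ratio is set to the odds of the threshold
probability, l/p := p_t/(1 − p_t), giving the net benefit
NB(p_t) = TP/N − odds(p_t)·FP/N.  The default grid is 0.01–0.99 in steps of
0.01; p_t = 1 is excluded because its odds diverge.  Treat-all has the
closed form prev − odds(p_t)(1 − prev); treat-none is identically zero.

The linear dose model has no probability axis.  By default its curve is
that of the fixed sign-rule classifier, whose NB varies with p_t only
through the false-positive weighting — the reading that needs no machinery
beyond the model itself.  Because a *fixed* classifier mathematically
cannot match threshold-adaptive classifiers at permissive thresholds, an
optional calibrated rendering (`linear_calibrated=True`) first maps the
predicted dose difference to a probability via a univariate logistic
regression of the label on the prediction, then thresholds it like any
other model.  The calibrated rendering is an interpretation and is labelled
as such wherever it is used.

**Bootstrap confidence bands.**  Percentile intervals at each grid point
from resamples (with replacement, default size = cohort size) of
(prediction, label) *pairs*, with the model fitted once and held fixed;
quantiles are linear-interpolation (type 7).  Holding the model fixed
matches computing NB "by definition" on resampled rows and isolates
evaluation uncertainty; `refit=True` refits per resample to fold in model
uncertainty, and `sample_size` decouples the resample size from the fitting
cohort.  Nested-simulation checks at n = 138 put the empirical coverage of
the fixed-model 95% interval for NB(0.3) at ~92% against the large-sample
truth (the suite recomputes this).

## Internal and external validation

Repeated random data splitting: per repetition a simple random split with
held-out size round((1 − train_frac)·n) (70/30 default: 41 of 138 held
out), the chosen model refit on the training part, decisions scored on the
held-out part.  Training splits with a single class are redrawn and
counted.  Both aggregations of the per-repetition metrics are reported —
mean over repetitions and pooled confusion counts — because they answer
slightly different questions and differ at the third decimal in practice.
Alongside error rates the pipeline pools the *misclassified dose*: |Δ| of
every wrongly assigned held-out patient.  Errors concentrate near Δ = 0
(mean misclassified |Δ| ≈ 0.7 Gy against ≈ 1.5 Gy cohort-wide at default
settings), which is the clinically reassuring failure mode a raw error rate
cannot show.  `external_evaluation` applies a frozen model to an
independent labelled cohort without refitting.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis needs, not
the anatomy it came from.  Covariates (bmi, a_heart, d_median, ptv) are
multivariate normal, truncated at physical lower bounds by rejection
sampling, with means (27 kg/m², 6 cm², 15 mm, 900 cm³) and SDs
(4.5, 4, 7, 330).  The correlation structure couples PTV to BMI (0.60) and
A_heart (0.35) — breast size tracks habitus — and A_heart negatively to
d_median (−0.45): a heart hugging the chest wall presents more area in the
field.  The dose difference follows the structural equation

```
Δ = β₀ + β_bmi·bmi + β_area·a_heart + β_dist·d_median + ε,  ε ~ N(0, σ²)
```

with defaults β₀ = −3.7, β_bmi = 0.115, β_area = 0.33 (Gy/cm²),
β_dist = −0.09 (Gy/mm), σ = 1.15 Gy.  PTV carries **no** structural effect;
its weak marginal discriminability arises purely through correlation.
Higher-order terms are deliberately absent — the linearity is an explicit
modelling assumption of the whole pipeline.  Positional doses are
back-filled (prone dose from a truncated normal, mean 4.5 Gy, SD 1.2 Gy;
supine = prone + Δ clipped at 0 with Δ re-recorded), which keeps records
internally consistent and never flips a label.  The heart-dose difference
is a noisy linear transform of Δ whose noise is sized from the *realized*
Δ spread (truncation and clipping shrink the analytic variance), hitting
the target correlation 0.87 within ±0.01 at n = 5000.

**Calibration.**  The defaults were fixed once, by simulation, to the
qualitative pattern the analysis assumes: univariate AUCs ordering
A_heart (≈ 0.86) > d_median (≈ 0.76) > BMI (≈ 0.72) > PTV (≈ 0.65),
multivariate logistic AUC ≈ 0.90, supine prevalence ≈ 0.47, and 70/30
cross-validated sensitivity/specificity of the linear model ≈ 0.78/0.85 at
n = 138.  These are properties of the synthetic population — not estimates
of any clinical cohort's parameters — and the dose scale (Δ SD ≈ 1.75 Gy)
was chosen jointly with the prone-dose floor so the nonnegativity clip
touches only ~2% of patients and leaves regression recovery unbiased at
test tolerances.

**What passing tests do not show.**  The generator is symmetric and
Gaussian where real dosimetry is skewed (large positive Δ tails in
unfavourable supine anatomies), has no measurement error in the covariates,
and no site effects.  Tests passing on it demonstrate that the *methods*
are implemented correctly and behave as theory predicts under their own
assumptions — not that the fitted coefficients or error rates transfer to
any clinic's population.

## Numerical choices and degenerate inputs

* Problem sizes: calibration-structure checks run at n = 5000 (AUC SE
  ≈ 0.008, small enough to resolve every ordered gap), parameter recovery
  at n = 5000 × 20 seeds, coverage at 200 × (n = 138, 500 resamples),
  study-scale runs at n = 138 with 1000 bootstrap resamples and 1000
  splits — the same resampling depths the analysis is specified with.
* Per-stage seeds spawn deterministically from one global seed via
  `SeedSequence.spawn`, so any stage reproduces in isolation from the run
  manifest.
* Exact ties: label ties → 0; linear predictions at exactly 0 → prone;
  Youden ties → higher specificity; `score ≥ t` everywhere.
* Zero-variance predictors, single-class cohorts, rank-deficient designs,
  empty grids, p_t = 1, all-zero Brier weights and empty cohorts raise
  typed errors naming the offender; undefined measures propagate as NaN.
* CSV I/O preserves full float precision (round-trip exact); malformed rows
  are reported with their file row numbers.

## Known limitations

* The stepwise procedure refits only the fixed-term model inside
  cross-validation splits by default; re-running selection per split would
  measure selection instability as well, at ~4× the cost.
* DeLong intervals are asymptotic; at n = 28-scale external cohorts they
  are indicative only.
* The bootstrap band quantifies evaluation uncertainty of a fixed model;
  it is not a prediction interval for a new cohort's net benefit.
* The generator's covariate distribution is a modelling convenience; only
  the induced discriminability pattern, not the covariate law, is
  calibrated.
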