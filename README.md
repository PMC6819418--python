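# posedca

**Decision-curve evaluation of prediction models for supine vs prone
breast-irradiation positioning.**

## The problem

In left-sided breast radiotherapy the dose absorbed by the left anterior
descending coronary artery (LAD) depends strongly on whether the patient is
treated supine or prone, and the better position varies from patient to
patient.  The reference ("gold standard") way to decide is to acquire CT
series and make treatment plans in *both* positions and compare the LAD
mean doses — expensive in scanner time, physician workload and extra imaging
dose.  The quantity that drives the decision is the **LAD mean dose
difference**

```
Δ = D̄_LAD(supine) − D̄_LAD(prone)   [Gy]
```

with Δ > 0 favouring prone (coded 0) and Δ < 0 favouring supine (coded 1).

`posedca` builds and evaluates models that predict this decision from four
easily measured patient characteristics: BMI (kg/m²), the in-field heart
area on a single mid-heart supine CT slice A_heart (cm²), the median
LAD–chest-wall distance d_median (mm), and the planning target volume PTV
(cm³, a proxy for breast size).  Because the underlying clinical dataset is
not public, the package ships a calibrated, seedable synthetic-cohort
generator with the same statistical structure, so the whole analysis is
reproducible end to end.

## What it computes

* **Candidate models** — univariate logistic regressions per predictor; the
  *main-effect* logistic model `a_heart + bmi + d_median`; a logistic model
  with only the interaction products `a_heart·bmi + a_heart·d_median`;
  stepwise logistic selection by likelihood-ratio tests (forward/backward);
  and a multiple linear regression of Δ itself whose binary decision is the
  *sign* of the predicted difference.  Predictor clustering (1 − |Pearson r|,
  average linkage) supports choosing poorly correlated predictors.
* **Performance metrics** — sensitivity/specificity/PPV/NPV/accuracy, the
  Youden index J = se + sp − 1 and its maximizing cut-point, tie-corrected
  Mann–Whitney ROC-AUC with DeLong 95% CI, and (weighted) Brier scores
  BS = Σ wᵢ(pᵢ − oᵢ)² / Σ wᵢ.
* **Decision curves** — the net benefit

  ```
  NB(p_t) = TP/N − p_t/(1 − p_t) · FP/N
  ```

  over a threshold-probability grid, against treat-all / treat-none
  references, with percentile-bootstrap confidence bands (pairs resampled,
  model held fixed).
* **Internal validation** — 1000 random 70/30 train/test splits with
  per-repetition sensitivity/specificity and the pooled *misclassified
  dose* distribution (|Δ| of wrongly assigned held-out patients), plus a
  harness for frozen-model evaluation on external cohorts.

## Worked example

Run the whole synthetic study in one command:

```bash
posedca -v reproduce --outdir run-demo --seed 1
```

This generates a 138-patient virtual cohort, clusters the predictors, fits
all seven candidate models, and writes the metrics table, decision-curve
table + figure, bootstrap net-benefit bounds and cross-validation summary
(~5 s).  The metrics table (`run-demo/model_metrics.csv`) starts:

```
model,key,auc,auc_ci_low,auc_ci_high,brier
PTV (univariate),ptv,0.701,0.612,0.791,0.214
BMI (univariate),bmi,0.733,0.650,0.816,0.209
Median distance (univariate),d_median,0.734,0.650,0.818,0.205
Area (univariate),a_heart,0.882,0.825,0.938,0.138
```

(values rounded here; the file holds full precision) — no single predictor
is good enough on its own, the in-field heart area is the strongest, and
the multivariate rows below reach AUC ≈ 0.91.  The cross-validation summary
(`run-demo/crossval_summary.json`) reports for the linear dose model

```
"mean_sensitivity": 0.797,  "mean_specificity": 0.875
```

over 1000 held-out splits, and shows that misclassified patients carry a
mean |Δ| of 0.68 Gy versus 1.67 Gy cohort-wide: the errors concentrate where
the two positions hardly differ, i.e. where a wrong call is clinically
cheapest.  `run-demo/decision_curves.csv` holds every plotted net-benefit
series; the multivariate curves lie above every univariate curve across the
clinically plausible threshold range.

The same stages are available piecemeal (`simulate`, `fit`, `predict`,
`evaluate`, `dca`, `crossval`), and everything is importable:

```python
from posedca import (default_calibrated_config, generate_cohort,
                     fit_logistic_main_effect, decision_curve, bootstrap_nb_ci)

cohort = generate_cohort(default_calibrated_config(n=138), seed=1)
model = fit_logistic_main_effect(cohort)
curve = decision_curve({"main": model}, cohort)
lo, hi = bootstrap_nb_ci(model, cohort, n_boot=1000, seed=1)
```

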