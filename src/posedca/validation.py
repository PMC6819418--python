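"""Internal validation by repeated random data splitting, plus an external harness.

A model evaluated on its own training data looks better than it is.  The
internal validation here repeatedly splits the cohort at random into a
training part (default 70%) and a held-out part (default 30%), refits the
chosen model on the training part, and scores its position decisions on the
held-out part against the gold-standard labels.

Binary error rates hide the clinical cost of a mistake, so alongside
sensitivity/specificity/accuracy each repetition also records the
*misclassified dose*: |LAD mean dose difference| of every held-out patient
assigned the wrong position.  Errors concentrated near 0 Gy are clinically
cheap; errors at large |difference| are the ones that matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cohort import LabelledCohort
from .metrics import basic_measures, confusion_at_threshold, ConfusionCounts
from .models import (
    FittedModel,
    ModelError,
    fit_linear_dose_model,
    fit_logistic_interaction,
    fit_logistic_main_effect,
    fit_univariate_logistic,
    predict,
)

MODEL_KINDS = ("linear", "main-effect", "interaction")


def _fitter_for(model_kind: str) -> Callable[[LabelledCohort], FittedModel]:
    if model_kind == "linear":
        return fit_linear_dose_model
    if model_kind == "main-effect":
        return fit_logistic_main_effect
    if model_kind == "interaction":
        return fit_logistic_interaction
    if model_kind.startswith("univariate:"):
        name = model_kind.split(":", 1)[1]
        return lambda cohort: fit_univariate_logistic(cohort, name)
    raise ModelError(
        f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS} "
        "or 'univariate:<predictor>'"
    )


@dataclass(frozen=True)
class SplitValidationSummary:
    """Held-out performance over repeated random splits.

    ``sensitivity``/``specificity``/``accuracy`` are per-repetition vectors
    (NaN where the held-out split lacked the relevant class);
    ``misclassified_doses`` pools |dose_diff| (Gy) of every misclassified
    held-out patient across repetitions.  ``pooled_counts`` tallies all
    held-out decisions into one confusion matrix, giving the alternative
    pooled-count aggregation alongside the mean-over-repetitions one.
    ``redrawn_splits`` counts splits redrawn because the training part
    contained a single class.  ``resubstitution`` holds the apparent
    (train = test = full cohort) measures for the same model kind.
    """

    n_reps: int
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    misclassified_doses: np.ndarray
    pooled_counts: ConfusionCounts
    redrawn_splits: int
    resubstitution: dict

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))

    def pooled_measures(self) -> dict:
        m = basic_measures(self.pooled_counts)
        return {
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "accuracy": m.accuracy,
        }


def _decide(fitted: FittedModel, cohort: LabelledCohort, idx: np.ndarray) -> np.ndarray:
    sub = LabelledCohort(
        tuple(cohort.records[i] for i in idx), cohort.dose_diff[idx], cohort.label[idx]
    )
    return predict(fitted, sub).decision


def repeated_split_validation(
    cohort: LabelledCohort,
    model_kind: str = "linear",
    train_frac: float = 0.7,
    n_reps: int = 1000,
    seed: int = 0,
    max_redraws: int = 1000,
) -> SplitValidationSummary:
    """Repeated random train/test splitting with misclassified-dose tracking.

    Each repetition draws a simple random split with a held-out size of
    ``round((1 - train_frac) * n)``, refits ``model_kind`` on the training
    part, and scores held-out decisions.  Splits whose training part has a
    single class are redrawn (counted in ``redrawn_splits``).  Same seed,
    same summary, bit for bit.
    """
    if not 0.0 < train_frac < 1.0:
        raise ModelError("train_frac must lie in (0, 1)")
    n = len(cohort)
    n_test = int(round((1.0 - train_frac) * n))
    if n_test < 1 or n - n_test < 2:
        raise ModelError(f"cohort of {n} is too small for a {train_frac:.0%} split")
    fitter = _fitter_for(model_kind)
    rng = np.random.default_rng(seed)

    sens = np.empty(n_reps)
    spec = np.empty(n_reps)
    acc = np.empty(n_reps)
    missed: list[np.ndarray] = []
    pooled = np.zeros(4, dtype=int)  # tp, fp, fn, tn
    redraws = 0

    for rep in range(n_reps):
        for _ in range(max_redraws + 1):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if len(np.unique(cohort.label[train_idx])) == 2:
                break
            redraws += 1
        else:
            raise ModelError("could not draw a two-class training split")
        train = LabelledCohort(
            tuple(cohort.records[i] for i in train_idx),
            cohort.dose_diff[train_idx],
            cohort.label[train_idx],
        )
        fitted = fitter(train)
        decisions = _decide(fitted, cohort, test_idx)
        truth = cohort.label[test_idx]
        tp = int(np.sum((decisions == 1) & (truth == 1)))
        fp = int(np.sum((decisions == 1) & (truth == 0)))
        fn = int(np.sum((decisions == 0) & (truth == 1)))
        tn = int(np.sum((decisions == 0) & (truth == 0)))
        pooled += (tp, fp, fn, tn)
        sens[rep] = tp / (tp + fn) if tp + fn else np.nan
        spec[rep] = tn / (tn + fp) if tn + fp else np.nan
        acc[rep] = (tp + tn) / n_test
        wrong = test_idx[decisions != truth]
        if wrong.size:
            missed.append(np.abs(cohort.dose_diff[wrong]))

    full_fit = fitter(cohort)
    full_dec = predict(full_fit, cohort).decision
    resub_counts = ConfusionCounts(
        tp=int(np.sum((full_dec == 1) & (cohort.label == 1))),
        fp=int(np.sum((full_dec == 1) & (cohort.label == 0))),
        fn=int(np.sum((full_dec == 0) & (cohort.label == 1))),
        tn=int(np.sum((full_dec == 0) & (cohort.label == 0))),
    )
    rm = basic_measures(resub_counts)

    return SplitValidationSummary(
        n_reps=n_reps,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        misclassified_doses=(
            np.concatenate(missed) if missed else np.empty(0, dtype=float)
        ),
        pooled_counts=ConfusionCounts(*pooled),
        redrawn_splits=redraws,
        resubstitution={
            "sensitivity": rm.sensitivity,
            "specificity": rm.specificity,
            "accuracy": rm.accuracy,
        },
    )


def misclassified_dose_summary(s: SplitValidationSummary) -> dict:
    """Mean, median and 90th percentile of the pooled misclassified |dose_diff|.

    All NaN when no held-out patient was ever misclassified.
    """
    d = s.misclassified_doses
    if d.size == 0:
        return {"mean": np.nan, "median": np.nan, "p90": np.nan, "count": 0}
    return {
        "mean": float(np.mean(d)),
        "median": float(np.median(d)),
        "p90": float(np.quantile(d, 0.9)),
        "count": int(d.size),
    }


def external_evaluation(model: FittedModel, external_cohort: LabelledCohort):
    """Apply a frozen model to an external cohort.

    Returns (ConfusionCounts, accuracy).  The model is not refitted; the
    external table must carry the model's covariates and gold-standard
    labels.
    """
    decisions = predict(model, external_cohort).decision
    truth = external_cohort.label
    counts = ConfusionCounts(
        tp=int(np.sum((decisions == 1) & (truth == 1))),
        fp=int(np.sum((decisions == 1) & (truth == 0))),
        fn=int(np.sum((decisions == 0) & (truth == 1))),
        tn=int(np.sum((decisions == 0) & (truth == 0))),
    )
    return counts, (counts.tp + counts.tn) / counts.n
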