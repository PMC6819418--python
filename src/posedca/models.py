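"""Candidate position-prediction models and their decision rules.

Five model families compete to predict the preferable irradiation position
(1 = supine, 0 = prone) from anatomy covariates:

* univariate logistic regressions (one per candidate predictor);
* the three-predictor "main effect" logistic model
  ``a_heart + bmi + d_median``;
* a logistic model with exactly the two interaction products
  ``a_heart*bmi`` and ``a_heart*d_median`` and no main effects;
* stepwise logistic selection by likelihood-ratio tests (forward or
  backward), the procedure that produced the two multivariate logistic
  models above in the first place;
* a multiple linear regression of the continuous LAD mean dose difference
  on ``a_heart + bmi + d_median``, whose binary decision is the *sign* of
  the predicted difference (predicted positive -> prone).

Logistic decisions threshold the predicted probability of "supine
preferred" at 0.5 by default (overridable).  Complete separation is not
fatal: the affected fit is re-run with standardized coefficients capped at
|15| and flagged, so resampling loops stay alive.

Predictor clustering (agglomerative, distance ``1 - |Pearson r|``, average
linkage) supports choosing poorly correlated predictors before model
building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.cluster.hierarchy import linkage as _linkage
from scipy.spatial.distance import squareform

from .cohort import LabelledCohort

MAIN_EFFECT_TERMS = ("a_heart", "bmi", "d_median")
INTERACTION_TERMS = ("a_heart:bmi", "a_heart:d_median")

#: cap on |standardized slope| used when a logistic fit separates
SEPARATION_CAP = 15.0


class ModelError(ValueError):
    """Raised for unfittable models (single class, rank deficiency, ...)."""


@dataclass(frozen=True)
class FittedModel:
    """A fitted candidate model plus the rule turning predictions into decisions.

    ``coefficients`` holds the intercept first, then one value per entry of
    ``terms`` (a term may be an interaction product written ``"a:b"``).
    ``bse`` are the corresponding standard errors; ``llf`` the log-likelihood
    at the optimum (logistic kinds).
    """

    kind: str  # univariate-logistic | logistic-main-effect | logistic-interaction
    #      | stepwise-logistic | linear-regression
    terms: tuple[str, ...]
    coefficients: np.ndarray
    decision_rule: str
    threshold: float = 0.5
    separation: bool = False
    bse: np.ndarray | None = None
    llf: float | None = None
    step_log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.shape != (len(self.terms) + 1,):
            raise ModelError("coefficients must be intercept + one value per term")

    @property
    def is_logistic(self) -> bool:
        return self.kind != "linear-regression"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "terms": list(self.terms),
            "coefficients": self.coefficients.tolist(),
            "decision_rule": self.decision_rule,
            "threshold": self.threshold,
            "separation": self.separation,
            "step_log": list(self.step_log),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            kind=d["kind"],
            terms=tuple(d["terms"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            decision_rule=d["decision_rule"],
            threshold=d.get("threshold", 0.5),
            separation=d.get("separation", False),
            step_log=tuple(d.get("step_log", ())),
        )


@dataclass(frozen=True)
class PredictorClustering:
    """Pairwise Pearson similarity and the agglomerative merge history."""

    names: tuple[str, ...]
    similarity: np.ndarray  # Pearson r, symmetric, unit diagonal
    merges: np.ndarray  # scipy linkage matrix over 1 - |r| distances


@dataclass(frozen=True)
class Predictions:
    """Per-patient model output.

    ``value`` is a probability of "supine preferred" for logistic kinds and
    a predicted dose difference in Gy for the linear kind; ``decision`` is
    the binary position call (1 = supine, 0 = prone).
    """

    value: np.ndarray
    decision: np.ndarray


def _frame_of(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    if hasattr(data, "frame"):  # LabelledCohort or compatible
        return data.frame
    return pd.DataFrame([r.__dict__ for r in data])


def term_values(frame: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate a term name (plain covariate or ':'-joined product)."""
    out = np.ones(len(frame))
    for part in term.split(":"):
        if part not in frame.columns:
            raise ModelError(f"missing covariate {part!r}")
        col = frame[part].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ModelError(f"covariate {part!r} contains missing values")
        out = out * col
    return out


def design_matrix(frame: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(frame))]
    cols += [term_values(frame, t) for t in terms]
    return np.column_stack(cols)


def cluster_predictors(
    cohort: LabelledCohort, predictors: Sequence[str] = ("bmi", "a_heart", "d_median", "ptv")
) -> PredictorClustering:
    """Agglomerative clustering of predictors by Pearson similarity.

    Distance is ``1 - |r|`` (absolute correlation: multicollinearity is a
    problem regardless of sign) with average linkage.  The full merge
    history is returned so the analyst can pick poorly correlated subsets.
    """
    if len(predictors) < 2:
        raise ModelError("need at least 2 predictors to cluster")
    if len(cohort) < 3:
        raise ModelError("need at least 3 patients to estimate correlations")
    frame = cohort.frame
    x = np.column_stack([term_values(frame, p) for p in predictors])
    sds = x.std(axis=0)
    for name, sd in zip(predictors, sds):
        if sd == 0:
            raise ModelError(f"predictor {name!r} has zero variance")
    r = np.corrcoef(x, rowvar=False)
    dist = np.clip(1.0 - np.abs(r), 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    merges = _linkage(squareform(dist, checks=False), method="average")
    return PredictorClustering(tuple(predictors), r, merges)


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ModelError("both position classes must be present to fit a logistic model")


def _logit_nll(beta, x, y):
    eta = x @ beta
    # log(1 + exp(eta)) - y*eta, computed stably
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _fit_logistic(x: np.ndarray, y: np.ndarray):
    """ML logistic fit with a capped fallback under separation.

    Returns (coefficients, bse, llf, separation_flag).  The fallback
    standardizes the design, maximizes the likelihood with slopes bounded
    at +/- SEPARATION_CAP, and maps back to the raw scale.
    """
    sds = x[:, 1:].std(axis=0, ddof=0)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, x).fit(disp=0, maxiter=200)
            if not result.mle_retvals.get("converged", False):
                result = None
        except Exception:
            result = None
    if result is not None:
        std_slopes = result.params[1:] * sds
        if np.all(np.abs(std_slopes) < SEPARATION_CAP) and np.all(
            np.isfinite(result.bse)
        ):
            return result.params, result.bse, float(result.llf), False

    # separation (or non-convergence): bounded refit on standardized design
    means = x[:, 1:].mean(axis=0)
    safe_sds = np.where(sds > 0, sds, 1.0)
    z = np.column_stack([x[:, 0], (x[:, 1:] - means) / safe_sds])
    bounds = [(None, None)] + [(-SEPARATION_CAP, SEPARATION_CAP)] * (x.shape[1] - 1)
    res = optimize.minimize(
        _logit_nll, np.zeros(x.shape[1]), args=(z, y), method="L-BFGS-B", bounds=bounds
    )
    beta_std = res.x
    slopes = beta_std[1:] / safe_sds
    intercept = beta_std[0] - float(np.sum(slopes * means))
    params = np.concatenate([[intercept], slopes])
    llf = -_logit_nll(beta_std, z, y)
    bse = np.full(x.shape[1], np.nan)
    return params, bse, float(llf), True


def _logistic_model(cohort: LabelledCohort, terms, kind, threshold=0.5) -> FittedModel:
    frame = _frame_of(cohort)
    y = cohort.label.astype(float)
    _check_labels(y)
    x = design_matrix(frame, terms)
    for t, sd in zip(terms, x[:, 1:].std(axis=0)):
        if sd == 0:
            raise ModelError(f"predictor {t!r} has zero variance")
    params, bse, llf, sep = _fit_logistic(x, y)
    return FittedModel(
        kind=kind,
        terms=tuple(terms),
        coefficients=params,
        decision_rule=f"supine (1) iff P(supine) >= {threshold}",
        threshold=threshold,
        separation=sep,
        bse=bse,
        llf=llf,
    )


def fit_univariate_logistic(
    cohort: LabelledCohort, predictor: str, threshold: float = 0.5
) -> FittedModel:
    """Logistic regression of the position label on a single predictor."""
    return _logistic_model(cohort, (predictor,), "univariate-logistic", threshold)


def fit_logistic_main_effect(cohort: LabelledCohort, threshold: float = 0.5) -> FittedModel:
    """The main-effect logistic model: a_heart + bmi + d_median."""
    return _logistic_model(cohort, MAIN_EFFECT_TERMS, "logistic-main-effect", threshold)


def fit_logistic_interaction(cohort: LabelledCohort, threshold: float = 0.5) -> FittedModel:
    """Logistic model with only a_heart*bmi and a_heart*d_median products."""
    return _logistic_model(cohort, INTERACTION_TERMS, "logistic-interaction", threshold)


def stepwise_logistic(
    cohort: LabelledCohort,
    candidate_terms: Sequence[str],
    direction: str = "forward",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    threshold: float = 0.5,
) -> FittedModel:
    """Stepwise logistic selection by likelihood-ratio chi-square tests.

    Forward: repeatedly add the candidate with the smallest LR p-value while
    it is below ``p_enter``.  Backward: start from the full model and
    repeatedly drop the term with the largest LR p-value while it exceeds
    ``p_remove``.  A step whose fit fails is skipped and logged.  Returns the
    selected model (kind ``stepwise-logistic``) with a human-readable step
    log.
    """
    if direction not in ("forward", "backward"):
        raise ModelError(f"unknown direction {direction!r}")
    if not candidate_terms:
        raise ModelError("candidate_terms must be nonempty")
    frame = _frame_of(cohort)
    y = cohort.label.astype(float)
    _check_labels(y)

    log: list[str] = []

    def llf_of(terms) -> float | None:
        try:
            x = design_matrix(frame, terms)
            params, _, llf, sep = _fit_logistic(x, y)
            if sep:
                log.append(f"separation in fit of {terms or '(intercept)'}")
            return llf
        except Exception as exc:  # non-convergent / degenerate step
            log.append(f"skipped {terms}: {exc}")
            return None

    current: list[str] = list(candidate_terms) if direction == "backward" else []
    current_llf = llf_of(tuple(current))
    if current_llf is None:
        raise ModelError("initial stepwise fit failed")

    while True:
        if direction == "forward":
            pool = [t for t in candidate_terms if t not in current]
            best = None
            for t in pool:
                llf = llf_of(tuple(current) + (t,))
                if llf is None:
                    continue
                lr = max(2.0 * (llf - current_llf), 0.0)
                p = stats.chi2.sf(lr, df=1)
                if best is None or p < best[0]:
                    best = (p, t, llf)
            if best is None or best[0] >= p_enter:
                break
            p, t, llf = best
            current.append(t)
            current_llf = llf
            log.append(f"enter {t} (LR p={p:.3g})")
        else:
            if not current:
                break
            worst = None
            for t in current:
                reduced = tuple(u for u in current if u != t)
                llf = llf_of(reduced)
                if llf is None:
                    continue
                lr = max(2.0 * (current_llf - llf), 0.0)
                p = stats.chi2.sf(lr, df=1)
                if worst is None or p > worst[0]:
                    worst = (p, t, llf)
            if worst is None or worst[0] <= p_remove:
                break
            p, t, llf = worst
            current.remove(t)
            current_llf = llf
            log.append(f"remove {t} (LR p={p:.3g})")

    x = design_matrix(frame, tuple(current))
    params, bse, llf, sep = _fit_logistic(x, y)
    return FittedModel(
        kind="stepwise-logistic",
        terms=tuple(current),
        coefficients=params,
        decision_rule=f"supine (1) iff P(supine) >= {threshold}",
        threshold=threshold,
        separation=sep,
        bse=bse,
        llf=llf,
        step_log=tuple(log),
    )


def fit_linear_dose_model(
    cohort: LabelledCohort, terms: Sequence[str] = MAIN_EFFECT_TERMS
) -> FittedModel:
    """OLS of the LAD mean dose difference (Gy) on the anatomy predictors.

    The binary decision is the sign of the predicted difference: positive
    (supine dose higher) -> prone (0); negative -> supine (1); an exact zero
    prediction falls to prone, mirroring the gold-standard tie rule.
    """
    frame = _frame_of(cohort)
    x = design_matrix(frame, terms)
    if len(cohort) < x.shape[1] + 1:
        raise ModelError("too few patients for the linear dose model")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ModelError("design matrix is rank deficient")
    res = sm.OLS(cohort.dose_diff, x).fit()
    return FittedModel(
        kind="linear-regression",
        terms=tuple(terms),
        coefficients=res.params,
        decision_rule="sign of predicted dose difference",
        bse=res.bse,
        llf=float(res.llf),
    )


def calibrated_probabilities(model: FittedModel, cohort: LabelledCohort) -> np.ndarray:
    """Probability of "supine preferred" for any model kind.

    Logistic kinds return their fitted probabilities.  The linear kind has
    no native probability scale; it is *calibrated* by a univariate logistic
    regression of the cohort label on its predicted dose difference.  This
    is an interpretation layered on top of the sign rule, not part of the
    linear model itself; use it where a probability axis is required
    (Brier scores, probability-thresholded decision curves).
    """
    pred = predict(model, cohort)
    if model.is_logistic:
        return pred.value
    frame = pd.DataFrame({"_linear_prediction": pred.value})
    x = np.column_stack([np.ones(len(frame)), pred.value])
    params, _, _, _ = _fit_logistic(x, cohort.label.astype(float))
    eta = x @ params
    return 1.0 / (1.0 + np.exp(-eta))


def predict(model: FittedModel, data) -> Predictions:
    """Apply a fitted model to records / a cohort / a covariate DataFrame.

    Logistic kinds return the probability of "supine preferred" and call
    supine when it reaches ``model.threshold``.  The linear kind returns the
    predicted dose difference in Gy and calls supine exactly when the
    prediction is negative.
    """
    frame = _frame_of(data)
    x = design_matrix(frame, model.terms)
    eta = x @ model.coefficients
    if model.is_logistic:
        prob = 1.0 / (1.0 + np.exp(-eta))
        return Predictions(value=prob, decision=(prob >= model.threshold).astype(int))
    return Predictions(value=eta, decision=(eta < 0).astype(int))
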