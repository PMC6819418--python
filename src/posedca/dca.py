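"""Net benefit and decision curves with bootstrap confidence bands.

ROC-style measures weight false positives and false negatives equally.
Decision-curve analysis instead evaluates a classifier through a utility:
Peirce's benefit ``B = (profit*TP - loss*FP) / N`` where *profit* rewards a
true positive call and *loss* penalizes a false positive.  Profit and loss
are unmeasurable in most clinical settings, so the loss-to-profit ratio is
set to the odds of the threshold probability p_t at which the model's
predicted probability is called positive:

    l / p := p_t / (1 - p_t)

Normalizing the benefit by the profit then yields the *net benefit*

    NB(p_t) = TP/N - p_t/(1 - p_t) * FP/N

Plotting NB against p_t gives the decision curve; a model is clinically
useful at p_t where its curve lies above both reference strategies: call
everyone positive ("treat all") and call no one ("treat none", NB = 0).

Here the positive call is "supine preferred" (label 1).  Logistic models
are thresholded at each p_t; the linear dose-difference model classifies by
its sign rule regardless of p_t, so its curve varies with p_t only through
the false-positive weighting.  Percentile bootstrap bands resample
(prediction, label) pairs with the model held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import LabelledCohort
from .metrics import ConfusionCounts
from .models import FittedModel, predict


class DCAError(ValueError):
    """Raised for invalid decision-curve inputs."""


def default_grid(start: float = 0.01, stop: float = 0.99, step: float = 0.01) -> np.ndarray:
    """Threshold-probability grid, by default 0.01..0.99 in steps of 0.01.

    p_t = 1 is always excluded: its odds diverge.
    """
    grid = np.round(np.arange(start, stop + step / 2, step), 10)
    return grid[(grid > 0) & (grid < 1)]


def threshold_odds(p_t: float) -> float:
    """Loss-to-profit weighting implied by threshold probability p_t."""
    if not 0 <= p_t < 1:
        raise DCAError(f"threshold probability must lie in [0, 1), got {p_t}")
    return p_t / (1.0 - p_t)


def net_benefit(c: ConfusionCounts, p_t: float) -> float:
    """NB = TP/N - odds(p_t) * FP/N for one confusion tally."""
    w = threshold_odds(p_t)
    return c.tp / c.n - w * c.fp / c.n


def benefit_peirce(c: ConfusionCounts, profit: float, loss: float) -> float:
    """Peirce's benefit B = (profit*TP - loss*FP)/N.

    ``net_benefit(c, p_t)`` equals ``benefit_peirce(c, 1, odds(p_t))``: the
    net benefit is the benefit normalized by the profit, with the
    loss-to-profit ratio fixed at the threshold odds.
    """
    return (profit * c.tp - loss * c.fp) / c.n


@dataclass(frozen=True)
class NetBenefitPoint:
    p_t: float
    nb: float


@dataclass(frozen=True)
class DecisionCurve:
    """Per-model net benefit over a p_t grid with the two reference strategies."""

    grid: np.ndarray
    curves: dict[str, np.ndarray]  # model name -> NB series
    treat_all: np.ndarray
    treat_none: np.ndarray
    ci: dict[str, tuple[np.ndarray, np.ndarray]] | None = None


def _call_matrix(
    model: FittedModel,
    cohort: LabelledCohort,
    grid: np.ndarray,
    linear_calibrated: bool = False,
) -> np.ndarray:
    """Boolean (len(grid), n) matrix of positive (supine) calls.

    Logistic kinds call positive where probability >= p_t.  The linear
    kind's sign-rule calls are constant across the grid by default; with
    ``linear_calibrated`` its predictions are mapped to probabilities first
    (see :func:`posedca.models.calibrated_probabilities`) and thresholded
    like any other model.
    """
    pred = predict(model, cohort)
    if model.is_logistic:
        return pred.value[None, :] >= grid[:, None]
    if linear_calibrated:
        from .models import calibrated_probabilities

        prob = calibrated_probabilities(model, cohort)
        return prob[None, :] >= grid[:, None]
    return np.broadcast_to(pred.decision.astype(bool), (grid.size, len(cohort)))


def _nb_series(calls: np.ndarray, labels: np.ndarray, grid: np.ndarray) -> np.ndarray:
    n = labels.size
    pos = labels == 1
    tp = (calls & pos[None, :]).sum(axis=1)
    fp = (calls & ~pos[None, :]).sum(axis=1)
    w = grid / (1.0 - grid)
    return tp / n - w * fp / n


def decision_curve(
    models: Sequence[FittedModel] | dict[str, FittedModel],
    cohort: LabelledCohort,
    grid: np.ndarray | None = None,
    linear_calibrated: bool = False,
) -> DecisionCurve:
    """Decision curves for one or more fitted models on a labelled cohort.

    Includes the treat-all curve (everyone called supine) and the treat-none
    reference (identically zero).  ``models`` may be a name->model mapping;
    a plain sequence is named by model kind (suffixed when repeated).
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DCAError("threshold grid is empty")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise DCAError("threshold grid must lie strictly inside (0, 1)")

    if not isinstance(models, dict):
        named: dict[str, FittedModel] = {}
        for m in models:
            name, k = m.kind, 2
            while name in named:
                name, k = f"{m.kind}-{k}", k + 1
            named[name] = m
        models = named

    labels = cohort.label
    curves = {
        name: _nb_series(_call_matrix(m, cohort, grid, linear_calibrated), labels, grid)
        for name, m in models.items()
    }
    all_calls = np.ones((grid.size, len(cohort)), dtype=bool)
    return DecisionCurve(
        grid=grid,
        curves=curves,
        treat_all=_nb_series(all_calls, labels, grid),
        treat_none=np.zeros_like(grid),
    )


def treat_all_net_benefit(prevalence: float, p_t: float) -> float:
    """Closed form for the treat-all strategy: prev - odds(p_t)*(1 - prev)."""
    return prevalence - threshold_odds(p_t) * (1.0 - prevalence)


def bootstrap_nb_ci(
    model: FittedModel,
    cohort: LabelledCohort,
    grid: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    sample_size: int | None = None,
    refit: bool = False,
    ci_level: float = 0.95,
    linear_calibrated: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap bounds for the net benefit at every grid point.

    Default behaviour: the model is fitted once (the ``model`` argument) and
    held fixed; each of ``n_boot`` resamples draws ``sample_size`` (default:
    cohort size) patients with replacement and recomputes NB from the
    resampled (prediction, label) pairs.  ``refit=True`` instead refits the
    model's terms on every resample before predicting, capturing model
    uncertainty as well.  Quantiles are linear-interpolation (type 7)
    percentiles at (1 - ci_level)/2 and 1 - (1 - ci_level)/2.  Seeded and
    reproducible.
    """
    if n_boot < 2:
        raise DCAError("n_boot must be >= 2")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    size = n if sample_size is None else int(sample_size)
    labels = cohort.label

    nbs = np.empty((n_boot, grid.size))
    if refit:
        from . import models as _models

        fitters = {
            "logistic-main-effect": _models.fit_logistic_main_effect,
            "logistic-interaction": _models.fit_logistic_interaction,
            "linear-regression": _models.fit_linear_dose_model,
        }
        frame = cohort.frame
        for b in range(n_boot):
            idx = rng.integers(0, n, size=size)
            sub = LabelledCohort(
                tuple(cohort.records[i] for i in idx),
                cohort.dose_diff[idx],
                labels[idx],
            )
            if model.kind == "univariate-logistic":
                refitted = _models.fit_univariate_logistic(sub, model.terms[0])
            elif model.kind in fitters:
                refitted = fitters[model.kind](sub)
            else:
                raise DCAError(f"refit unsupported for kind {model.kind!r}")
            nbs[b] = _nb_series(_call_matrix(refitted, sub, grid), labels[idx], grid)
        lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
        return (
            np.quantile(nbs, lo_q, axis=0),
            np.quantile(nbs, hi_q, axis=0),
        )

    calls = _call_matrix(model, cohort, grid, linear_calibrated)  # (grid, n)
    pos = labels == 1
    tp_ind = calls & pos[None, :]
    fp_ind = calls & ~pos[None, :]
    w = grid / (1.0 - grid)
    idx = rng.integers(0, n, size=(n_boot, size))
    # accumulate per-resample TP/FP counts for every grid point
    for g in range(grid.size):
        tp = tp_ind[g][idx].sum(axis=1)
        fp = fp_ind[g][idx].sum(axis=1)
        nbs[:, g] = tp / size - w[g] * fp / size
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    return np.quantile(nbs, lo_q, axis=0), np.quantile(nbs, hi_q, axis=0)
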