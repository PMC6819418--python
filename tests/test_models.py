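"""Model fitting: clustering, logistic/linear estimation, stepwise selection, decisions."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from posedca.cohort import LabelledCohort
from posedca.models import (
    FittedModel,
    ModelError,
    cluster_predictors,
    calibrated_probabilities,
    design_matrix,
    fit_linear_dose_model,
    fit_logistic_interaction,
    fit_logistic_main_effect,
    fit_univariate_logistic,
    predict,
    stepwise_logistic,
)
from posedca.synthetic import default_calibrated_config, generate_cohort

from conftest import make_cohort


# ---------------------------------------------------------------- clustering

def test_identical_predictors_merge_at_zero_distance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100) + 25
    cohort = make_cohort({"bmi": x, "a_heart": x, "d_median": rng.normal(size=100) + 15},
                         label=rng.integers(0, 2, 100))
    clust = cluster_predictors(cohort, ("bmi", "a_heart", "d_median"))
    assert clust.similarity[0, 1] == pytest.approx(1.0)
    first = clust.merges[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_independent_predictors_merge_near_one():
    rng = np.random.default_rng(1)
    cohort = make_cohort(
        {"bmi": rng.normal(size=2000) + 25, "a_heart": rng.normal(size=2000) + 5},
        label=rng.integers(0, 2, 2000),
    )
    clust = cluster_predictors(cohort, ("bmi", "a_heart"))
    assert clust.merges[0, 2] == pytest.approx(1.0, abs=0.08)


def test_near_duplicate_merges_before_unrelated():
    rng = np.random.default_rng(2)
    x1 = rng.normal(size=500) + 25
    x3 = x1 + rng.normal(scale=0.05, size=500)
    x2 = rng.normal(size=500) + 15
    cohort = make_cohort({"bmi": x1, "d_median": x2, "ptv": 800 + x3},
                         label=rng.integers(0, 2, 500))
    clust = cluster_predictors(cohort, ("bmi", "d_median", "ptv"))
    # (bmi, ptv) = (x1, x3) merge first; d_median joins later
    assert {int(clust.merges[0, 0]), int(clust.merges[0, 1])} == {0, 2}


def test_zero_variance_predictor_named_in_error():
    cohort = make_cohort({"bmi": np.full(50, 25.0)}, label=[0, 1] * 25)
    with pytest.raises(ModelError, match="bmi"):
        cluster_predictors(cohort, ("bmi", "a_heart"))


# ---------------------------------------------------------------- logistic fits

def test_null_predictor_slope_within_three_se():
    rng = np.random.default_rng(3)
    n = 5000
    cohort = make_cohort({"bmi": rng.normal(size=n) + 25}, label=rng.integers(0, 2, n))
    model = fit_univariate_logistic(cohort, "bmi")
    assert abs(model.coefficients[1]) < 3 * model.bse[1]


def test_perfect_separation_is_flagged_not_fatal():
    label = np.array([0] * 20 + [1] * 20)
    cohort = make_cohort({"a_heart": label * 10.0 + 1.0}, label=label)
    model = fit_univariate_logistic(cohort, "a_heart")
    assert model.separation
    prob = predict(model, cohort).value
    assert np.all((prob > 0) & (prob < 1))
    # capped fit still separates the classes in practice
    assert np.all(prob[label == 1] > 0.99) and np.all(prob[label == 0] < 0.01)


def test_single_class_cohort_rejected():
    cohort = make_cohort({}, label=np.zeros(30, dtype=int))
    with pytest.raises(ModelError, match="classes"):
        fit_univariate_logistic(cohort, "bmi")


def test_row_duplication_leaves_coefficients_unchanged(default_cohort_138):
    model = fit_logistic_main_effect(default_cohort_138)
    doubled = LabelledCohort(
        default_cohort_138.records * 2,
        np.concatenate([default_cohort_138.dose_diff] * 2),
        np.concatenate([default_cohort_138.label] * 2),
    )
    doubled_model = fit_logistic_main_effect(doubled)
    np.testing.assert_allclose(model.coefficients, doubled_model.coefficients, atol=1e-6)


def test_patient_order_does_not_change_fit(default_cohort_138):
    c = default_cohort_138
    perm = np.random.default_rng(8).permutation(len(c))
    shuffled = LabelledCohort(
        tuple(c.records[i] for i in perm), c.dose_diff[perm], c.label[perm]
    )
    a = fit_logistic_interaction(c)
    b = fit_logistic_interaction(shuffled)
    np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8)


def test_null_coefficients_recovered_when_effects_absent():
    cfg = replace(default_calibrated_config(n=5000), beta_bmi=0.0, beta_dist=0.0)
    cohort = generate_cohort(cfg, seed=13)
    model = fit_logistic_main_effect(cohort)
    terms = dict(zip(model.terms, zip(model.coefficients[1:], model.bse[1:])))
    for name in ("bmi", "d_median"):
        coef, se = terms[name]
        assert abs(coef) < 3 * se


def test_interaction_model_equals_reparametrized_fit():
    """With a_heart constant = c the interaction fit is a logistic fit on scaled columns."""
    rng = np.random.default_rng(5)
    n = 400
    bmi = rng.normal(size=n) + 25
    dist = rng.normal(size=n) + 15
    eta = 0.8 * (bmi - 25) - 0.5 * (dist - 15)
    label = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    c = 3.0
    cohort = make_cohort({"a_heart": np.full(n, c), "bmi": bmi, "d_median": dist}, label=label)
    inter = fit_logistic_interaction(cohort)
    probs_inter = predict(inter, cohort).value

    scaled = make_cohort({"bmi": c * bmi, "d_median": c * dist}, label=label)
    from posedca.models import _logistic_model

    direct = _logistic_model(scaled, ("bmi", "d_median"), "univariate-logistic")
    probs_direct = predict(direct, scaled).value
    np.testing.assert_allclose(probs_inter, probs_direct, atol=1e-6)


def test_loglik_gradient_vanishes_at_optimum(default_cohort_138):
    """Score equations X'(y - p) = 0 hold at the reported MLE (standardized design)."""
    model = fit_logistic_main_effect(default_cohort_138)
    x = design_matrix(default_cohort_138.frame, model.terms)
    prob = predict(model, default_cohort_138).value
    # standardize columns to make the tolerance scale-free
    xs = x.copy()
    xs[:, 1:] = (x[:, 1:] - x[:, 1:].mean(axis=0)) / x[:, 1:].std(axis=0)
    grad = xs.T @ (default_cohort_138.label - prob) / len(default_cohort_138)
    assert np.max(np.abs(grad)) < 1e-6


def _brute_force_logistic_mle(x1: np.ndarray, y: np.ndarray):
    """Two-stage grid search over (intercept, slope) of the log-likelihood."""
    def nll(b0, b1):
        eta = b0 + b1 * x1
        return np.sum(np.logaddexp(0.0, eta) - y * eta)

    best = (np.inf, 0.0, 0.0)
    grid0 = np.linspace(-10, 10, 201)
    for b0 in grid0:
        for b1 in grid0:
            v = nll(b0, b1)
            if v < best[0]:
                best = (v, b0, b1)
    _, b0, b1 = best
    for half_width in (0.1, 0.01, 0.001):
        g0 = np.linspace(b0 - 10 * half_width, b0 + 10 * half_width, 41)
        g1 = np.linspace(b1 - 10 * half_width, b1 + 10 * half_width, 41)
        best = (np.inf, b0, b1)
        for a in g0:
            for b in g1:
                v = nll(a, b)
                if v < best[0]:
                    best = (v, a, b)
        _, b0, b1 = best
    return b0, b1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_logistic_mle_matches_grid_search_on_tiny_cohorts(seed):
    rng = np.random.default_rng(seed)
    n = 10
    x = rng.normal(size=n)
    label = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
    if len(np.unique(label)) < 2:
        label[0], label[-1] = 0, 1
    cohort = make_cohort({"bmi": x + 25}, label=label)
    model = fit_univariate_logistic(cohort, "bmi")
    if model.separation:
        pytest.skip("separated draw; grid comparison undefined")
    b0, b1 = _brute_force_logistic_mle(x + 25 - 25, label.astype(float))
    # grid search works on the centred covariate; map the fit accordingly
    fitted_b1 = model.coefficients[1]
    fitted_b0 = model.coefficients[0] + 25 * fitted_b1
    assert fitted_b0 == pytest.approx(b0, abs=2e-3)
    assert fitted_b1 == pytest.approx(b1, abs=2e-3)


# ---------------------------------------------------------------- linear model

def test_noise_free_cohort_recovers_generator_betas_exactly():
    cfg = replace(default_calibrated_config(n=200), noise_sd=0.0,
                  lad_prone_mean=15.0, lad_prone_sd=0.5)  # keep the dose clip inactive
    cohort = generate_cohort(cfg, seed=6)
    assert not np.any(np.array([r.lad_supine for r in cohort.records]) == 0)
    model = fit_linear_dose_model(cohort)
    expected = {"a_heart": cfg.beta_area, "bmi": cfg.beta_bmi, "d_median": cfg.beta_dist}
    assert model.coefficients[0] == pytest.approx(cfg.beta0, abs=1e-8)
    for term, coef in zip(model.terms, model.coefficients[1:]):
        assert coef == pytest.approx(expected[term], abs=1e-8)


def test_constant_shift_moves_only_the_intercept(default_cohort_138):
    c = default_cohort_138
    base = fit_linear_dose_model(c)
    shifted_records = tuple(
        replace(r, lad_supine=None, lad_prone=None) for r in c.records
    )
    shifted = LabelledCohort(shifted_records, c.dose_diff + 5.0,
                             (c.dose_diff + 5.0 < 0).astype(int))
    moved = fit_linear_dose_model(shifted)
    assert moved.coefficients[0] - base.coefficients[0] == pytest.approx(5.0, abs=1e-8)
    np.testing.assert_allclose(moved.coefficients[1:], base.coefficients[1:], atol=1e-8)


def test_rank_deficient_design_rejected():
    x = np.arange(30, dtype=float)
    cohort = make_cohort({"bmi": x + 20, "a_heart": 2 * x + 1, "d_median": x + 5},
                         dose_diff=x - 15)
    # a_heart and bmi are collinear (a_heart = 2*bmi - 39)
    with pytest.raises(ModelError, match="rank"):
        fit_linear_dose_model(cohort)


# ---------------------------------------------------------------- stepwise

def test_forward_selection_finds_strong_single_effect():
    rng = np.random.default_rng(17)
    n = 5000
    cols = {k: rng.normal(size=n) + 20 for k in ("bmi", "a_heart", "d_median", "ptv")}
    eta = 1.5 * (cols["a_heart"] - 20)
    label = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    cohort = make_cohort(cols, label=label)
    model = stepwise_logistic(cohort, ("bmi", "a_heart", "d_median", "ptv"), "forward")
    assert "a_heart" in model.terms
    assert model.terms[0] == "a_heart"


def test_backward_from_single_informative_term_retains_it():
    rng = np.random.default_rng(18)
    n = 2000
    x = rng.normal(size=n)
    label = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
    cohort = make_cohort({"bmi": x + 25}, label=label)
    model = stepwise_logistic(cohort, ("bmi",), "backward")
    assert model.terms == ("bmi",)


def test_forward_then_backward_is_idempotent():
    rng = np.random.default_rng(19)
    n = 3000
    cols = {k: rng.normal(size=n) + 20 for k in ("bmi", "a_heart", "d_median")}
    eta = 1.2 * (cols["a_heart"] - 20) - 0.8 * (cols["d_median"] - 20)
    label = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    cohort = make_cohort(cols, label=label)
    fwd = stepwise_logistic(cohort, ("bmi", "a_heart", "d_median"), "forward",
                            p_enter=0.05, p_remove=0.05)
    back = stepwise_logistic(cohort, fwd.terms, "backward", p_enter=0.05, p_remove=0.05)
    assert set(back.terms) == set(fwd.terms)


def test_stepwise_rejects_bad_inputs(default_cohort_138):
    with pytest.raises(ModelError, match="direction"):
        stepwise_logistic(default_cohort_138, ("bmi",), "sideways")
    with pytest.raises(ModelError, match="nonempty"):
        stepwise_logistic(default_cohort_138, (), "forward")


# ---------------------------------------------------------------- prediction

@pytest.mark.parametrize("pred, decision", [(3.2, 0), (-0.1, 1), (0.0, 0)])
def test_linear_sign_rule(pred, decision):
    model = FittedModel(
        kind="linear-regression", terms=("bmi",),
        coefficients=np.array([pred, 0.0]),
        decision_rule="sign of predicted dose difference",
    )
    frame = pd.DataFrame({"bmi": [25.0]})
    out = predict(model, frame)
    assert out.value[0] == pytest.approx(pred)
    assert out.decision[0] == decision


def test_null_logistic_model_predicts_half():
    model = FittedModel(
        kind="logistic-main-effect", terms=("a_heart", "bmi", "d_median"),
        coefficients=np.zeros(4), decision_rule="p >= 0.5",
    )
    frame = pd.DataFrame({"a_heart": [1.0, 9.0], "bmi": [20.0, 35.0], "d_median": [5.0, 30.0]})
    np.testing.assert_allclose(predict(model, frame).value, 0.5)


def test_missing_covariate_named_in_error():
    model = FittedModel(
        kind="univariate-logistic", terms=("a_heart",),
        coefficients=np.array([0.0, 1.0]), decision_rule="p >= 0.5",
    )
    with pytest.raises(ModelError, match="a_heart"):
        predict(model, pd.DataFrame({"bmi": [25.0]}))


def test_model_json_round_trip(default_cohort_138):
    model = fit_logistic_main_effect(default_cohort_138)
    back = FittedModel.from_dict(model.to_dict())
    np.testing.assert_allclose(back.coefficients, model.coefficients)
    assert back.terms == model.terms and back.kind == model.kind


def test_calibrated_probabilities_monotone_in_linear_prediction(default_cohort_138):
    model = fit_linear_dose_model(default_cohort_138)
    pred = predict(model, default_cohort_138).value
    prob = calibrated_probabilities(model, default_cohort_138)
    order = np.argsort(pred)
    # lower predicted dose difference => supine more likely => higher probability
    assert np.all(np.diff(prob[order]) <= 1e-12)
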