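"""End-to-end synthetic-study orchestration.

:func:`reproduce_study` runs the whole pipeline on one virtual cohort:
generate -> cluster predictors -> fit every candidate model -> ROC/Brier
report -> decision curves with bootstrap confidence bands -> repeated-split
cross-validation.  Every stage draws its randomness from a per-stage seed
spawned deterministically from the single global seed (via
``numpy.random.SeedSequence(global_seed).spawn``), so any stage can be
re-run in isolation from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dca, metrics, models, validation
from .cohort import LabelledCohort, write_cohort_csv
from .synthetic import GeneratorConfig, default_calibrated_config, generate_cohort

log = logging.getLogger("posedca")

#: order of the per-predictor / per-model rows in the metrics report
REPORT_ROWS = (
    ("ptv", "PTV (univariate)"),
    ("bmi", "BMI (univariate)"),
    ("d_median", "Median distance (univariate)"),
    ("a_heart", "Area (univariate)"),
    ("main-effect", "Logistic regression (main effect model)"),
    ("interaction", "Logistic regression (interaction model)"),
    ("linear", "Linear regression"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic-study run."""

    generator: GeneratorConfig = field(default_factory=default_calibrated_config)
    grid_min: float = 0.01
    grid_max: float = 0.99
    grid_step: float = 0.01
    n_boot: int = 1000
    cv_reps: int = 1000
    train_frac: float = 0.7
    outdir: str = "posedca-run"
    seed: int = 0

    def grid(self) -> np.ndarray:
        return dca.default_grid(self.grid_min, self.grid_max, self.grid_step)


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from one global seed.

    Children of ``SeedSequence(global_seed)`` in a fixed order; each stage
    seed is the child's first 31-bit state word, so stages are independent
    and individually reproducible.
    """
    names = ("cohort", "bootstrap", "crossval", "external")
    children = np.random.SeedSequence(global_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for name, child in zip(names, children)
    }


def fit_all_models(cohort: LabelledCohort) -> dict[str, models.FittedModel]:
    """Fit the seven candidate models reported by the pipeline."""
    fitted: dict[str, models.FittedModel] = {}
    for name in ("ptv", "bmi", "d_median", "a_heart"):
        fitted[name] = models.fit_univariate_logistic(cohort, name)
    fitted["main-effect"] = models.fit_logistic_main_effect(cohort)
    fitted["interaction"] = models.fit_logistic_interaction(cohort)
    fitted["linear"] = models.fit_linear_dose_model(cohort)
    return fitted


def model_score(model: models.FittedModel, cohort: LabelledCohort) -> np.ndarray:
    """Orientation-correct score for ROC analysis.

    Logistic kinds: predicted probability of supine.  Linear kind: the
    negated predicted dose difference (more negative difference -> supine
    more likely -> higher score).
    """
    pred = models.predict(model, cohort)
    return pred.value if model.is_logistic else -pred.value


def model_probability(model: models.FittedModel, cohort: LabelledCohort) -> np.ndarray:
    """Probability of "supine preferred" for the Brier score.

    The linear kind carries no native probability; it is calibrated through
    a univariate logistic regression of the label on its predicted dose
    difference (an interpretation, recorded as such in the report).
    """
    return models.calibrated_probabilities(model, cohort)


def metrics_report(fitted: dict[str, models.FittedModel], cohort: LabelledCohort) -> pd.DataFrame:
    """Per-model AUC (with DeLong 95% CI) and Brier score, report-ordered."""
    rows = []
    for key, label in REPORT_ROWS:
        model = fitted[key]
        roc = metrics.roc_curve_auc(model_score(model, cohort), cohort.label)
        brier = metrics.brier_score(model_probability(model, cohort), cohort.label)
        rows.append(
            {
                "model": label,
                "key": key,
                "auc": roc.auc,
                "auc_ci_low": roc.ci95[0],
                "auc_ci_high": roc.ci95[1],
                "brier": brier,
            }
        )
    return pd.DataFrame(rows)


def nb_ci_table(
    model: models.FittedModel,
    cohort: LabelledCohort,
    n_boot: int,
    seed: int,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bootstrap percentile bounds for net benefit at coarse thresholds."""
    thresholds = np.round(np.arange(0.1, 0.95, 0.1), 10) if thresholds is None else thresholds
    lower, upper = dca.bootstrap_nb_ci(model, cohort, thresholds, n_boot=n_boot, seed=seed)
    curve = dca.decision_curve({"model": model}, cohort, thresholds)
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "net_benefit": curve.curves["model"],
            "nb_lower": lower,
            "nb_upper": upper,
        }
    )


def _plot_decision_curves(curve: dca.DecisionCurve, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, nb in curve.curves.items():
        ax.plot(curve.grid, nb, label=name, lw=1.4)
    ax.plot(curve.grid, curve.treat_all, "k--", lw=1, label="treat all (supine)")
    ax.plot(curve.grid, curve.treat_none, "k:", lw=1, label="treat none")
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.05, float(np.nanmin(curve.treat_all)) * 0.2))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def reproduce_study(config: RunConfig) -> dict:
    """Run the full synthetic study and write every artifact to ``config.outdir``.

    Emits the cohort CSV, per-model coefficient JSONs, the AUC/Brier metrics
    table, the decision-curve CSV and figure, the bootstrap net-benefit CI
    table for the main-effect model, the cross-validation summary, and a
    manifest recording the configuration and every stage seed.  Returns the
    manifest as a dict.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    timings: dict[str, float] = {}

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        return t0

    t0 = stage("cohort")
    generator = replace(config.generator, seed=seeds["cohort"])
    cohort = generate_cohort(generator)
    write_cohort_csv(cohort, out / "cohort.csv")
    timings["cohort"] = time.perf_counter() - t0

    t0 = stage("cluster")
    clustering = models.cluster_predictors(cohort)
    (out / "predictor_clustering.json").write_text(
        json.dumps(
            {
                "predictors": list(clustering.names),
                "pearson_similarity": clustering.similarity.tolist(),
                "merge_history": clustering.merges.tolist(),
            },
            indent=2,
        )
    )
    timings["cluster"] = time.perf_counter() - t0

    t0 = stage("fit")
    fitted = fit_all_models(cohort)
    stepwise = {
        direction: models.stepwise_logistic(
            cohort, models.MAIN_EFFECT_TERMS + ("ptv",), direction=direction
        )
        for direction in ("forward", "backward")
    }
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    for name, model in {**fitted, **{f"stepwise-{d}": m for d, m in stepwise.items()}}.items():
        (model_dir / f"{name}.json").write_text(json.dumps(model.to_dict(), indent=2))
    timings["fit"] = time.perf_counter() - t0

    t0 = stage("metrics")
    report = metrics_report(fitted, cohort)
    report.to_csv(out / "model_metrics.csv", index=False)
    timings["metrics"] = time.perf_counter() - t0

    t0 = stage("dca")
    grid = config.grid()
    curve = dca.decision_curve(fitted, cohort, grid)
    curve_frame = pd.DataFrame({"threshold": grid})
    for name, nb in curve.curves.items():
        curve_frame[name] = nb
    curve_frame["treat_all"] = curve.treat_all
    curve_frame["treat_none"] = curve.treat_none
    curve_frame.to_csv(out / "decision_curves.csv", index=False)
    _plot_decision_curves(curve, out / "decision_curves.png")
    ci_table = nb_ci_table(fitted["main-effect"], cohort, config.n_boot, seeds["bootstrap"])
    ci_table.to_csv(out / "net_benefit_ci.csv", index=False)
    timings["dca"] = time.perf_counter() - t0

    t0 = stage("crossval")
    cv = validation.repeated_split_validation(
        cohort,
        model_kind="linear",
        train_frac=config.train_frac,
        n_reps=config.cv_reps,
        seed=seeds["crossval"],
    )
    dose_summary = validation.misclassified_dose_summary(cv)
    cv_payload = {
        "n_reps": cv.n_reps,
        "mean_sensitivity": cv.mean_sensitivity,
        "mean_specificity": cv.mean_specificity,
        "mean_accuracy": cv.mean_accuracy,
        "pooled": cv.pooled_measures(),
        "resubstitution": cv.resubstitution,
        "redrawn_splits": cv.redrawn_splits,
        "misclassified_dose": dose_summary,
    }
    (out / "crossval_summary.json").write_text(json.dumps(cv_payload, indent=2))
    hist, edges = np.histogram(
        cv.misclassified_doses, bins=np.arange(0.0, 10.5, 0.5)
    ) if cv.misclassified_doses.size else (np.zeros(20, dtype=int), np.arange(0.0, 10.5, 0.5))
    pd.DataFrame(
        {"bin_low_gy": edges[:-1], "bin_high_gy": edges[1:], "count": hist}
    ).to_csv(out / "misclassified_dose_hist.csv", index=False)
    timings["crossval"] = time.perf_counter() - t0

    manifest = {
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "generator": json.loads(generator.to_json()),
        "grid": {"min": config.grid_min, "max": config.grid_max, "step": config.grid_step},
        "n_boot": config.n_boot,
        "cv": {"reps": config.cv_reps, "train_frac": config.train_frac},
        "stepwise_selected": {d: list(m.terms) for d, m in stepwise.items()},
        "artifacts": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        ),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for name, elapsed in timings.items():
        log.info("stage %-9s %6.2fs", name, elapsed)
    return manifest
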