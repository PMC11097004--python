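"""End-to-end experiment orchestration.

Two top-level experiments mirror the study design:

* :func:`run_calibration_experiment` — synthesise a labelled calibration set,
  derive the eight factorial training datasets, fit and evaluate a random
  forest on each, and tabulate macro F +/- SEM with OOB error (the model
  comparison table) plus per-behaviour precision/recall/F.
* :func:`run_freeranging_comparison` — simulate free-ranging deployments,
  estimate each individual's activity budget with a reference labelling
  (rule tree on the first 15 min of each hour, as a field observer would
  label) and with each RF model, and report ICC(A,1) agreement per model,
  with and without the dominant rest behaviour.

Every stage draws its seed from one root seed; rerunning a config reproduces
identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .budget import (ICCResult, TimeBudget, compare_methods,
                     first_15min_per_hour, time_budget)
from .classify import (RFConfig, TrainedModel, classify_rule_tree,
                       default_rule_tree, evaluate, predict_rf, train_rf)
from .config import ExperimentConfig
from .datasets import DatasetVariant, derive_all_variants, split_train_test
from .features import build_bout_features, build_features, to_1hz
from .synthetic import (BEHAVIOURS, DeploymentConfig, generate_calibration_set,
                        generate_deployment, labels_per_sample)

log = logging.getLogger(__name__)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class CalibrationResult:
    summary: pd.DataFrame            # one row per variant: macro F, SEM, OOB %
    per_behaviour: pd.DataFrame      # per variant x behaviour: P / R / F
    models: dict[str, TrainedModel]
    variants: dict[str, DatasetVariant]
    manifest: dict = field(default_factory=dict)


def run_calibration_experiment(cfg: ExperimentConfig | None = None
                               ) -> CalibrationResult:
    """Train and validate the eight factorial RF models on synthetic data."""
    cfg = cfg or ExperimentConfig()
    seeds = _stage_seeds(cfg.seed, 4)
    gen_seed, derive_seed, split_seed, rf_seed = seeds

    log.info("stage simulate: %d individuals, %.0f s of behaviour",
             cfg.calibration.n_individuals,
             sum(cfg.calibration.per_behaviour_s.values()))
    traces, segments = generate_calibration_set(
        cfg.calibration.n_individuals, cfg.calibration.per_behaviour_s,
        seed=gen_seed, sample_rate_hz=cfg.calibration.sample_rate_hz,
        regimes=cfg.regimes)

    log.info("stage featurize: %d bouts", len(segments))
    frame40 = build_bout_features(
        traces, segments, "extended",
        static_window_s=cfg.features.static_window_s,
        smooth_window_s=cfg.features.smooth_window_s,
        se_window_s=cfg.features.se_window_s)

    log.info("stage derive: 8 factorial variants")
    variants = derive_all_variants(frame40, seed=derive_seed,
                                   cap_s=cfg.datasets.cap_s)

    summary_rows, detail_rows, models = [], [], {}
    for vid, variant in variants.items():
        train, test = split_train_test(
            variant, cfg.datasets.train_fraction, seed=split_seed,
            by_bout=cfg.datasets.split_by_bout)
        log.info("stage train [%s]: %d train / %d test records",
                 vid, len(train), len(test))
        rf_cfg = RFConfig(cfg.rf.n_trees, cfg.rf.predictors_per_split,
                          cfg.rf.min_node_train, cfg.rf.min_node_predict,
                          seed=rf_seed)
        model = train_rf(train[["behaviour", *variant.variable_columns]], rf_cfg,
                         variables=list(variant.variable_columns))
        pred = predict_rf(model, test)
        metrics = evaluate(pred, test["behaviour"].to_numpy(),
                           labels=sorted(set(variant.records["behaviour"])),
                           oob_error_pct=model.oob_error_pct)
        models[vid] = model
        fast = [b for b in ("walk", "trot", "run", "shake")
                if b in metrics.confusion.index]
        summary_rows.append((vid, variant.variables, variant.duration_policy,
                             variant.frequency, metrics.macro_f,
                             metrics.macro_f_complete,
                             metrics.macro_f_over(fast), metrics.sem_f,
                             model.oob_error_pct))
        for b in metrics.precision:
            detail_rows.append((vid, b, metrics.precision[b], metrics.recall[b],
                                metrics.f[b]))

    summary = pd.DataFrame(summary_rows, columns=[
        "variant", "variables", "duration_policy", "frequency_hz",
        "macro_f", "macro_f_complete", "fast_f", "sem_f", "oob_error_pct"])
    per_behaviour = pd.DataFrame(detail_rows, columns=[
        "variant", "behaviour", "precision", "recall", "f_measure"])
    manifest = {"seed": cfg.seed, "stage_seeds": seeds,
                "n_bouts": len(segments),
                "per_variant_records": {v.id: len(v.records)
                                        for v in variants.values()}}
    return CalibrationResult(summary, per_behaviour, models, variants, manifest)


@dataclass
class FreeRangingResult:
    budgets: pd.DataFrame   # individual x behaviour x source percentages
    icc: pd.DataFrame       # per model x (all | no_rest): estimate, CI, category
    manifest: dict = field(default_factory=dict)


def _budget_from_predictions(labels: np.ndarray, t: np.ndarray,
                             deployment_s: float, individual_id: str,
                             source: str, subsample: bool) -> TimeBudget:
    if subsample:
        mask = first_15min_per_hour(t)
        labels = labels[mask]
    return time_budget(labels, 0.0, deployment_s, individual_id, source)


def run_freeranging_comparison(cfg: ExperimentConfig | None = None,
                               calibration: CalibrationResult | None = None
                               ) -> FreeRangingResult:
    """Compare rule-tree and RF activity budgets on synthetic deployments."""
    cfg = cfg or ExperimentConfig()
    if calibration is None:
        calibration = run_calibration_experiment(cfg)
    dep_seeds = _stage_seeds(cfg.seed ^ 0x5EED, cfg.deployment.n_deployments)
    rule_tree = default_rule_tree()
    duration_days = cfg.deployment.effective_duration_days

    budget_rows = []
    ref_budgets: list[TimeBudget] = []
    model_budgets: dict[str, list[TimeBudget]] = {vid: [] for vid in calibration.models}
    for i in range(cfg.deployment.n_deployments):
        iid = f"roam{i + 1:02d}"
        dep_cfg = DeploymentConfig(duration_days, dict(cfg.deployment.budget),
                                   dict(cfg.deployment.mean_bout_s),
                                   seed=dep_seeds[i] % (2 ** 31))
        trace, segments = generate_deployment(
            dep_cfg, cfg.calibration.sample_rate_hz, cfg.regimes, iid)
        deployment_s = trace.duration_s
        log.info("deployment %s: %.1f h, %d bouts", iid, deployment_s / 3600,
                 len(segments))

        frame40 = build_features(trace, "extended",
                                 cfg.features.static_window_s,
                                 cfg.features.smooth_window_s,
                                 cfg.features.se_window_s)
        frame1 = to_1hz(frame40)

        # reference labelling: manual rule tree on the first 15 min of each hour
        if cfg.comparison.reference == "rule_tree":
            ref_labels = classify_rule_tree(frame40, rule_tree)
        elif cfg.comparison.reference == "truth":
            ref_labels = labels_per_sample(segments, trace.t)
        else:
            raise ValueError(f"unknown reference {cfg.comparison.reference!r}")
        ref = _budget_from_predictions(
            ref_labels, frame40.data["time_s"].to_numpy(), deployment_s, iid,
            "rule_tree", cfg.comparison.subsample_first_15min)
        ref_budgets.append(ref)
        budget_rows.append(ref.to_frame())

        truth = time_budget(labels_per_sample(segments, trace.t), 0.0,
                            deployment_s, iid, "truth")
        budget_rows.append(truth.to_frame())

        for vid, model in calibration.models.items():
            frame = frame40 if calibration.variants[vid].frequency == 40 else frame1
            pred = predict_rf(model, frame.data)
            b = time_budget(pred, 0.0, deployment_s, iid, vid)
            model_budgets[vid].append(b)
            budget_rows.append(b.to_frame())

    icc_rows = []
    for vid, budgets in model_budgets.items():
        for exclude, tag in ((frozenset(), "all"), (frozenset({"rest"}), "no_rest")):
            if tag == "no_rest" and not cfg.comparison.exclude_rest_rerun:
                continue
            try:
                res: ICCResult = compare_methods(ref_budgets, budgets, exclude)
                icc_rows.append((vid, tag, res.estimate, res.ci95_low,
                                 res.ci95_high, res.category))
            except ValueError as err:
                log.warning("ICC undefined for %s (%s): %s", vid, tag, err)
                icc_rows.append((vid, tag, np.nan, np.nan, np.nan, "undefined"))

    budgets = pd.concat(budget_rows, ignore_index=True)
    icc = pd.DataFrame(icc_rows, columns=[
        "variant", "behaviours", "icc", "ci95_low", "ci95_high", "category"])
    manifest = {"seed": cfg.seed, "deployment_seeds": dep_seeds,
                "duration_days": duration_days,
                "n_deployments": cfg.deployment.n_deployments}
    return FreeRangingResult(budgets, icc, manifest)
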