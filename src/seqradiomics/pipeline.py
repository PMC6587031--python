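"""End-to-end orchestration: simulate -> extract -> sequential -> select ->
classify, shared by the CLI and the test harness."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from seqradiomics.config import PipelineConfig
from seqradiomics.extract import extract_all_features
from seqradiomics.models import (CVPlan, ModelReport, build_model_zoo,
                                 repeated_cv_accuracy)
from seqradiomics.selection import (RadScoreModel, SelectionResult,
                                    TwoStageSelector, task_labels,
                                    two_stage_select)
from seqradiomics.simulate import CohortSpec, generate_image_cohort
from seqradiomics.types import FeatureTable

log = logging.getLogger("seqradiomics")


@dataclass
class PipelineResult:
    table: FeatureTable
    selection: SelectionResult
    report: ModelReport
    rad_scores: np.ndarray
    rad_model: RadScoreModel
    selector: TwoStageSelector | None = None
    timings: dict = field(default_factory=dict)


def classify_selected(table: FeatureTable, config: PipelineConfig,
                      selector: TwoStageSelector | None = None,
                      permute_labels: bool = False) -> ModelReport:
    """Repeated-CV comparison of the 20-model zoo on the selected features.

    With ``config.nested`` the selector is re-fitted inside every training
    fold; otherwise ``selector`` must already be fitted on the full table
    (the modeled study's sequence). ``permute_labels`` evaluates the same
    harness on label-shuffled data as a chance-level reference.
    """
    y = task_labels(table.labels, config.task)
    if permute_labels:
        rng = np.random.default_rng(config.seed)
        y = rng.permutation(y)
    plan = CVPlan(folds=config.cv_folds, rounds=config.cv_rounds,
                  seed=config.seed)
    if config.nested:
        nested_selector = TwoStageSelector(
            task=config.task, acceptance_factors=config.acceptance_factors,
            auto_tune=config.auto_tune_factors, top_k=config.fine_top_k,
            corr_threshold=config.corr_threshold,
            final_count=config.final_feature_count,
            cv_folds=config.cv_folds, seed=config.seed)
        zoo = build_model_zoo(config.task,
                              n_features=config.final_feature_count,
                              seed=config.seed)
        return repeated_cv_accuracy(table.values, y, zoo, plan,
                                    selector=nested_selector)
    if selector is None:
        raise ValueError("a fitted selector is required unless nested=True")
    X = selector.transform(table.values)
    zoo = build_model_zoo(config.task, n_features=X.shape[1], seed=config.seed)
    return repeated_cv_accuracy(X, y, zoo, plan)


def run_all_on_table(table: FeatureTable,
                     config: PipelineConfig) -> PipelineResult:
    """select -> classify -> rad-score on an existing feature table."""
    timings = {}
    t0 = time.perf_counter()
    selector, selection = two_stage_select(table, config)
    timings["select"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = classify_selected(table, config, selector)
    timings["classify"] = time.perf_counter() - t0

    y = task_labels(table.labels, config.task)
    X_final = selector.transform(table.values)
    rad = RadScoreModel(seed=config.seed).fit(X_final, y)
    scores = rad.decision_function(X_final)
    return PipelineResult(table, selection, report, scores, rad,
                          selector=selector, timings=timings)


def run_all(cohort_spec: CohortSpec, config: PipelineConfig) -> PipelineResult:
    """Full phantom pipeline from image simulation to the model report."""
    t0 = time.perf_counter()
    cohort = generate_image_cohort(cohort_spec)
    log.info("simulated %d subjects", len(cohort))
    table = extract_all_features(cohort, bin_count=config.bin_count)
    extract_s = time.perf_counter() - t0
    log.info("extracted %d features for %d subjects in %.1fs",
             table.n_features, table.n_subjects, extract_s)
    result = run_all_on_table(table, config)
    result.timings["simulate_extract"] = extract_s
    return result
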