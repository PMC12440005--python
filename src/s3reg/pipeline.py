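"""End-to-end convenience flows: standardize → tune → fit → post-hoc select.

These wrappers wire the modules together the way the CLI and the simulation
benchmark use them, keeping the individual pieces composable for anyone who
needs a different arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import (
    RunConfig,
    SpatialDataset,
    destandardize_values,
    standardize_dataset,
)
from .graph import SpatialGraph, build_graph
from .model import (
    CoefficientField,
    FitResult,
    OptimizerConfig,
    PenaltyConfig,
    fit_s3r,
    hard_threshold,
)
from .posthoc import (
    SelectionResult,
    apply_selection,
    cluster_spots,
    default_n_clusters,
    refit_and_test,
)
from .tuning import TuningResult, make_spatial_blocks, tune_hyperparameters


@dataclass
class PipelineResult:
    fit: FitResult
    field: CoefficientField  # raw-scale, hard-thresholded
    selection: SelectionResult
    selected_field: CoefficientField  # raw-scale, post-hoc selected
    tuning: TuningResult | None
    graph: SpatialGraph


def fit_standardized(
    dataset: SpatialDataset,
    graph: SpatialGraph,
    penalties: PenaltyConfig,
    opt: OptimizerConfig | None = None,
    config: RunConfig | None = None,
) -> tuple[FitResult, CoefficientField]:
    """Fit on z-scored predictors / centred response, report raw-scale field."""
    config = config or RunConfig()
    work, info = standardize_dataset(
        dataset, config.standardize_predictors, config.center_response
    )
    result = fit_s3r(work, graph, penalties, opt)
    raw = CoefficientField(
        destandardize_values(result.field.values, info),
        list(result.field.spot_ids),
        list(result.field.predictor_names),
    )
    return result, raw


def run_pipeline(
    dataset: SpatialDataset,
    penalties: PenaltyConfig | None = None,
    opt: OptimizerConfig | None = None,
    config: RunConfig | None = None,
    tune: bool = False,
    n_trials: int = 30,
    n_blocks: int = 10,
    tune_opt: OptimizerConfig | None = None,
    tune_sampler: str = "adaptive",
    alpha: float = 0.05,
    seed: int = 0,
) -> PipelineResult:
    """Full flow on one section.

    With ``tune=True`` the penalty triple is chosen by spatially blocked CV
    (log-uniform random search at a reduced optimisation budget) before the
    final fit; otherwise ``penalties`` must be given.  The fitted field is
    hard-thresholded and screened by cluster-wise post-hoc OLS tests.
    """
    config = config or RunConfig(seed=seed)
    graph = build_graph(
        dataset.coords, kind=config.graph_kind, k=config.knn_k,
        auto_threshold=config.auto_threshold,
    )
    tuning_result = None
    if tune:
        work, _ = standardize_dataset(
            dataset, config.standardize_predictors, config.center_response
        )
        scheme = make_spatial_blocks(
            dataset.coords, n_blocks=min(n_blocks, dataset.n_spots), seed=seed
        )
        tuning_result = tune_hyperparameters(
            work,
            scheme,
            n_trials=n_trials,
            seed=seed,
            opt=tune_opt or OptimizerConfig(max_iter=400, early_stop_patience=400),
            graph_kind=config.graph_kind,
            knn_k=config.knn_k,
            sampler=tune_sampler,
        )
        penalties = PenaltyConfig(*tuning_result.best)
    if penalties is None:
        raise ValueError("either pass penalties or set tune=True")

    fit_result, raw_field = fit_standardized(dataset, graph, penalties, opt, config)
    thresholded = hard_threshold(raw_field)
    labels = cluster_spots(
        dataset.coords, default_n_clusters(dataset.n_spots), seed=seed
    )
    selection = refit_and_test(dataset, thresholded, labels, alpha=alpha)
    selected = apply_selection(thresholded, selection)
    return PipelineResult(
        fit=fit_result,
        field=thresholded,
        selection=selection,
        selected_field=selected,
        tuning=tuning_result,
        graph=graph,
    )
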