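"""Synthetic spatially-varying-coefficient data and recovery scoring.

The generator draws spot coordinates uniformly on the unit square, partitions
them into spatial clusters (Voronoi cells of random centres, horizontal
bands, or a checkerboard), assigns each *active* predictor a piecewise-
constant coefficient per cluster, and produces the response as
``y = sum_k x_k beta_k + N(0, noise_sd^2)`` with i.i.d. standard-normal
predictors.  Inactive predictors have identically-zero coefficient surfaces,
so both spatial-cluster recovery (ARI) and variable selection
(precision/recall) can be scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .dataset import SpatialDataset, ValidationError
from .model import CoefficientField
from .posthoc import SelectionResult


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated dataset."""

    cluster_labels: np.ndarray
    true_field: np.ndarray
    active_set: np.ndarray
    noise_sd: float
    seed: int


@dataclass
class RecoveryReport:
    ari: float
    selection_precision: float
    selection_recall: float
    coefficient_rmse_active: float


def _pattern_labels(
    coords: np.ndarray, pattern: str, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    n = coords.shape[0]
    if n_clusters == 1:
        return np.zeros(n, dtype=int)
    if pattern == "voronoi":
        centers = rng.uniform(size=(n_clusters, 2))
        d = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)
    if pattern == "bands":
        edges = np.linspace(0.0, 1.0, n_clusters + 1)[1:-1]
        return np.searchsorted(edges, coords[:, 1], side="right")
    if pattern == "checker":
        g = max(2, n_clusters)
        ix = np.minimum((coords[:, 0] * g).astype(int), g - 1)
        iy = np.minimum((coords[:, 1] * g).astype(int), g - 1)
        return (ix + iy) % n_clusters
    raise ValidationError(f"unknown pattern {pattern!r}")


def _draw_cluster_coefficients(
    n_clusters: int, n_active: int, coef_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """One coefficient per (cluster, active predictor) from the nonzero
    integer grid {-coef_scale, ..., +coef_scale} \\ {0}.

    Clusters are redrawn until no two share the same coefficient vector, so
    the cluster partition is identifiable from the coefficient surfaces.
    """
    scale = max(1, int(round(coef_scale)))
    choices = np.array([v for v in range(-scale, scale + 1) if v != 0], dtype=float)
    for _ in range(1000):
        coefs = rng.choice(choices, size=(n_clusters, n_active))
        if len({tuple(row) for row in coefs}) == n_clusters:
            return coefs
    raise ValidationError(
        "could not draw distinct cluster coefficient vectors; "
        "increase coef_scale or n_active"
    )


def simulate_dataset(
    n: int = 300,
    p: int = 20,
    n_active: int = 3,
    n_clusters: int = 2,
    pattern: str = "voronoi",
    noise_sd: float = 0.5,
    coef_scale: float = 2.0,
    seed: int = 0,
) -> tuple[SpatialDataset, SyntheticTruth]:
    """Generate one synthetic section with piecewise-constant coefficients."""
    if n_active > p:
        raise ValidationError("n_active cannot exceed p")
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(size=(n, 2))
    labels = _pattern_labels(coords, pattern, n_clusters, rng)
    active = np.sort(rng.choice(p, size=n_active, replace=False))
    cluster_coefs = _draw_cluster_coefficients(n_clusters, n_active, coef_scale, rng)
    true_field = np.zeros((n, p))
    true_field[:, active] = cluster_coefs[labels]
    X = rng.standard_normal(size=(n, p))
    y = (X * true_field).sum(axis=1)
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=n)
    dataset = SpatialDataset(
        spot_ids=[f"spot{i:05d}" for i in range(n)],
        coords=coords,
        response=y,
        predictors=X,
        predictor_names=[f"g{k:04d}" for k in range(p)],
        section_id=f"sim_seed{seed}",
    )
    truth = SyntheticTruth(
        cluster_labels=labels,
        true_field=true_field,
        active_set=active,
        noise_sd=float(noise_sd),
        seed=seed,
    )
    return dataset, truth


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (pair-counting ARI)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or labels_a.ndim != 1:
        raise ValidationError("label vectors must be 1-D and of equal length")
    if labels_a.size < 2:
        raise ValidationError("need at least two items")
    return float(adjusted_rand_score(labels_a, labels_b))


def estimate_coefficient_clusters(
    field: CoefficientField | np.ndarray,
    active_columns,
    n_clusters: int,
    seed: int = 0,
) -> np.ndarray:
    """Cluster spots by their fitted coefficients on the truly active columns.

    Benchmark convention: k-means with the true number of clusters on the
    rows of the fitted field restricted to active predictors.
    """
    values = field.values if isinstance(field, CoefficientField) else field
    sub = values[:, np.asarray(active_columns, dtype=int)]
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(sub)


def recovery_benchmark(
    dataset: SpatialDataset,
    truth: SyntheticTruth,
    fitted: CoefficientField,
    selection: SelectionResult | None = None,
    seed: int = 0,
) -> RecoveryReport:
    """Score a fit against the simulator's ground truth.

    ARI compares k-means clusters of the fitted field (on truly active
    columns) to the true spatial partition.  Precision/recall compare the
    post-hoc-selected predictor set (selected anywhere) to the true active
    set; if no selection is given, nonzero-anywhere columns of the fitted
    field are used.  RMSE is over truly-active entries only.
    """
    n_clusters = int(truth.cluster_labels.max()) + 1
    est = estimate_coefficient_clusters(fitted, truth.active_set, n_clusters, seed=seed)
    ari = adjusted_rand_index(truth.cluster_labels, est)

    if selection is not None:
        selected = selection.selected_mask.any(axis=0)
    else:
        selected = (fitted.values != 0).any(axis=0)
    truly_active = np.zeros(dataset.n_predictors, dtype=bool)
    truly_active[truth.active_set] = True
    tp = int((selected & truly_active).sum())
    precision = tp / int(selected.sum()) if selected.any() else 0.0
    recall = tp / int(truly_active.sum())

    active_mask = truth.true_field != 0
    if active_mask.any():
        rmse = float(
            np.sqrt(((fitted.values - truth.true_field)[active_mask] ** 2).mean())
        )
    else:
        rmse = 0.0
    return RecoveryReport(
        ari=ari,
        selection_precision=precision,
        selection_recall=recall,
        coefficient_rmse_active=rmse,
    )
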