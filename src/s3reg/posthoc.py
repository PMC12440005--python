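"""Post-hoc significance screening of the fitted coefficient field.

Penalised estimates carry shrinkage bias and no standard errors, so retained
coefficients are re-examined by refitting unpenalised least squares locally:
the section is partitioned into spatial clusters (k-means on coordinates,
assuming nearby spots share coefficient scales), and within each cluster the
response is regressed on the predictors whose fitted coefficient column is
nonzero anywhere in that cluster.  Per-predictor two-sided t-test p-values
are shared by all spots of the cluster, Benjamini–Hochberg adjusted jointly
across every (cluster, predictor) test, and coefficients whose adjusted p
fails the level are zeroed out of the selection mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .dataset import SpatialDataset, ValidationError
from .model import CoefficientField


@dataclass
class SelectionResult:
    """P-values and the resulting significance mask, cluster-granular.

    ``pvalues`` is 1.0 at untested entries; untested entries are never
    selected.  ``selected_mask[i, k]`` is true iff predictor ``k`` was tested
    in spot ``i``'s cluster, its adjusted p-value is below ``alpha``, and the
    fitted coefficient there is nonzero.
    """

    pvalues: np.ndarray
    adjusted_pvalues: np.ndarray
    selected_mask: np.ndarray
    cluster_labels: np.ndarray
    alpha: float


def cluster_spots(coords: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """K-means partition of the spot coordinates; deterministic given seed."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValidationError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if n_clusters == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(coords)


def default_n_clusters(n_spots: int) -> int:
    """Default post-hoc cluster count: max(10, n/50), capped at n."""
    return min(n_spots, max(10, n_spots // 50))


def refit_and_test(
    dataset: SpatialDataset,
    field: CoefficientField,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> SelectionResult:
    """Cluster-wise OLS refits with BH-adjusted two-sided t-tests.

    Within each cluster, the candidate predictors are those whose fitted
    coefficient column is nonzero anywhere in the cluster (the field must be
    hard-thresholded so that exact zeros exist).  An intercept is included in
    every refit.  Clusters with more candidates than spots are rank
    deficient and are skipped with a warning; their entries remain untested.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    n, p = dataset.n_spots, dataset.n_predictors
    if field.values.shape != (n, p):
        raise ValidationError("field shape does not match dataset")
    if labels.shape != (n,):
        raise ValidationError("cluster labels length does not match dataset")

    pvalues = np.ones((n, p))
    tested: list[tuple[int, int, float]] = []  # (cluster, predictor, raw p)
    for c in np.unique(labels):
        rows = np.where(labels == c)[0]
        active_cols = np.where((field.values[rows] != 0).any(axis=0))[0]
        if active_cols.size == 0:
            continue
        if active_cols.size >= rows.size:
            warnings.warn(
                f"cluster {c}: {active_cols.size} active predictors for "
                f"{rows.size} spots; refit is rank deficient, tests skipped",
                stacklevel=2,
            )
            continue
        Xc = sm.add_constant(dataset.predictors[np.ix_(rows, active_cols)])
        res = sm.OLS(dataset.response[rows], Xc).fit()
        # first parameter is the intercept
        for col, pv in zip(active_cols, res.pvalues[1:]):
            pv = float(np.nan_to_num(pv, nan=1.0))
            tested.append((int(c), int(col), pv))
            pvalues[rows, col] = pv

    adjusted = np.ones((n, p))
    if tested:
        raw = np.array([t[2] for t in tested])
        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        for (c, col, _), a in zip(tested, adj):
            adjusted[labels == c, col] = a

    selected = (adjusted < alpha) & (field.values != 0)
    return SelectionResult(
        pvalues=pvalues,
        adjusted_pvalues=adjusted,
        selected_mask=selected,
        cluster_labels=labels,
        alpha=alpha,
    )


def apply_selection(field: CoefficientField, selection: SelectionResult) -> CoefficientField:
    """Zero every coefficient the post-hoc test did not keep."""
    values = np.where(selection.selected_mask, field.values, 0.0)
    return CoefficientField(values, list(field.spot_ids), list(field.predictor_names))
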