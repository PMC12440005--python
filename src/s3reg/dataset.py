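"""Core in-memory containers for one spatial section.

A :class:`SpatialDataset` holds everything the regression needs for a single
tissue section: 2-D spot/cell coordinates, one response feature ``y(s_i)`` and
an ``n x p`` predictor matrix ``x_k(s_i)``.  Rows are always aligned by spot
identifier and kept in a deterministic (sorted) order so that repeated loads
of the same files produce byte-identical objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when inputs violate a structural precondition."""


class AlignmentError(ValidationError):
    """Raised when spot/gene identifier sets do not match across inputs."""


@dataclass
class SpatialDataset:
    """One section: coordinates, response vector and predictor matrix.

    Parameters
    ----------
    spot_ids
        Unique string identifiers, one per spatial location.
    coords
        ``(n, 2)`` array of spatial coordinates (any consistent length unit).
    response
        Length-``n`` response feature ``y(s_i)``.
    predictors
        ``(n, p)`` matrix of predictor features ``x_k(s_i)``.
    predictor_names
        ``p`` unique predictor labels.
    section_id
        Free-form section label used by multi-section analyses.
    """

    spot_ids: list[str]
    coords: np.ndarray
    response: np.ndarray
    predictors: np.ndarray
    predictor_names: list[str]
    section_id: str = "section"

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.predictors = np.atleast_2d(np.asarray(self.predictors, dtype=float))
        self.predictor_names = [str(g) for g in self.predictor_names]
        n = len(self.spot_ids)
        if n < 2:
            raise ValidationError("a spatial dataset needs at least 2 spots")
        if len(set(self.spot_ids)) != n:
            raise ValidationError("duplicate spot ids")
        if self.coords.shape != (n, 2):
            raise ValidationError(
                f"coords must be (n, 2) = ({n}, 2), got {self.coords.shape}"
            )
        if self.response.shape != (n,):
            raise ValidationError("response length does not match number of spots")
        if self.predictors.shape[0] != n:
            raise ValidationError("predictor rows do not match number of spots")
        if self.predictors.shape[1] != len(self.predictor_names):
            raise ValidationError("predictor_names length does not match columns")
        if len(set(self.predictor_names)) != len(self.predictor_names):
            raise ValidationError("duplicate predictor names")
        for name, arr in (
            ("coords", self.coords),
            ("response", self.response),
            ("predictors", self.predictors),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name}")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_predictors(self) -> int:
        return self.predictors.shape[1]

    def subset_spots(self, indices: Sequence[int]) -> "SpatialDataset":
        """Return a new dataset restricted to the given spot row indices."""
        idx = np.asarray(indices, dtype=int)
        return SpatialDataset(
            spot_ids=[self.spot_ids[i] for i in idx],
            coords=self.coords[idx],
            response=self.response[idx],
            predictors=self.predictors[idx],
            predictor_names=list(self.predictor_names),
            section_id=self.section_id,
        )

    def subset_predictors(self, columns: Sequence[int]) -> "SpatialDataset":
        cols = np.asarray(columns, dtype=int)
        return SpatialDataset(
            spot_ids=list(self.spot_ids),
            coords=self.coords,
            response=self.response,
            predictors=self.predictors[:, cols],
            predictor_names=[self.predictor_names[j] for j in cols],
            section_id=self.section_id,
        )


@dataclass
class RunConfig:
    """User-facing options shared by the loading and fitting entry points.

    ``graph_kind='auto'`` follows the default policy: a KNN graph (``knn_k``
    neighbours) for sections with at most ``auto_threshold`` spots, a minimum
    spanning tree above that.  ``min_expression_fraction`` is the prevalence
    filter: predictors with nonzero values in fewer than that fraction of
    spots are dropped (strictly-less removal; a predictor at exactly the
    boundary is retained).
    """

    graph_kind: str = "auto"
    knn_k: int = 7
    auto_threshold: int = 1000
    min_expression_fraction: float = 0.10
    standardize_predictors: bool = True
    center_response: bool = True
    log_normalize: bool = False
    orientation: str = "spots_by_genes"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.graph_kind not in {"knn", "mst", "auto"}:
            raise ValidationError(f"unknown graph_kind {self.graph_kind!r}")
        if self.orientation not in {"spots_by_genes", "genes_by_spots"}:
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if not 0.0 <= self.min_expression_fraction <= 1.0:
            raise ValidationError("min_expression_fraction must be in [0, 1]")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be positive")


@dataclass
class StandardizationInfo:
    """Per-column transform applied before fitting, needed to undo it after.

    Predictors are z-scored (columns with zero variance are left unscaled) and
    the response is mean-centred.  Because the model has no intercept, the fit
    runs on the transformed data and coefficients are mapped back to the raw
    predictor scale by dividing by the column standard deviation.
    """

    predictor_means: np.ndarray
    predictor_scales: np.ndarray
    response_mean: float


def standardize_dataset(
    dataset: SpatialDataset,
    standardize_predictors: bool = True,
    center_response: bool = True,
) -> tuple[SpatialDataset, StandardizationInfo]:
    """Z-score predictors and centre the response; return transform info."""
    X = dataset.predictors
    if standardize_predictors:
        means = X.mean(axis=0)
        scales = X.std(axis=0)
        scales = np.where(scales > 0, scales, 1.0)
    else:
        means = np.zeros(X.shape[1])
        scales = np.ones(X.shape[1])
    y_mean = float(dataset.response.mean()) if center_response else 0.0
    transformed = replace(
        dataset,
        response=dataset.response - y_mean,
        predictors=(X - means) / scales,
        spot_ids=list(dataset.spot_ids),
        predictor_names=list(dataset.predictor_names),
    )
    return transformed, StandardizationInfo(means, scales, y_mean)


def destandardize_values(values: np.ndarray, info: StandardizationInfo) -> np.ndarray:
    """Map an ``n x p`` coefficient matrix back to the raw predictor scale."""
    return values / info.predictor_scales[np.newaxis, :]
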