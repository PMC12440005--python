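"""Spatially smooth sparse regression: objective and first-order solver.

The model regresses a spatial response on high-dimensional spatial predictors
with a coefficient that is allowed to vary over locations,

.. math::

    y(s_i) = \\sum_{k=1}^p x_k(s_i)\\,\\beta_k(s_i) + \\epsilon(s_i),

and estimates the stacked coefficient field by minimising

.. math::

    \\frac1n\\sum_i \\Big(y(s_i)-\\sum_k x_k(s_i)\\beta_k(s_i)\\Big)^2
    + \\lambda_1 \\sum_k \\lVert H\\beta_k\\rVert_1
    + \\lambda_2 \\sum_k \\lVert \\beta_k\\rVert_1
    + \\lambda_3 \\sum_k \\sqrt{n}\\,\\lVert \\beta_k\\rVert_2,

where ``H`` is the edge–node incidence operator of a spatial graph (KNN or
MST).  The three penalties respectively enforce spatial coherence of each
coefficient surface (piecewise-constant structure with sharp boundaries),
location-level sparsity, and removal of globally non-predictive features.

The objective is convex but non-smooth; it is minimised with an
adaptive-moment (Adam) first-order method using subgradients for the L1 and
fused terms and an epsilon-smoothed surrogate
``sqrt(||beta_k||^2 + eps)`` for the group norm.  Cosine or step learning-rate
schedules, global-norm gradient clipping and patience-based early stopping
keep the iteration stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import SpatialDataset, ValidationError
from .graph import IncidenceMatrix, SpatialGraph, incidence_matrix


class DivergenceError(RuntimeError):
    """Raised when the objective becomes non-finite during training."""


@dataclass
class PenaltyConfig:
    """Strengths of the three penalties.

    ``group_weight`` multiplies the group-L2 term for every predictor; the
    default ``None`` resolves to ``sqrt(n)`` at fit time (the standard
    group-lasso group-size weight, each group being one predictor's length-n
    coefficient vector).
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: float = 0.0
    group_weight: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValidationError("penalty strengths must be nonnegative")

    def resolve_group_weight(self, n: int) -> float:
        return math.sqrt(n) if self.group_weight is None else float(self.group_weight)


@dataclass
class OptimizerConfig:
    max_iter: int = 5000
    learning_rate: float = 0.01
    schedule: str = "cosine"  # cosine | step | constant
    grad_clip_norm: Optional[float] = 5.0
    epsilon_stab: float = 1e-8
    early_stop_patience: int = 50
    check_every: int = 25
    tol: float = 1e-6
    seed: int = 0
    batch_mode: bool = False
    batch_size: int = 256
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.schedule not in {"cosine", "step", "constant"}:
            raise ValidationError(f"unknown schedule {self.schedule!r}")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.early_stop_patience < 1:
            raise ValidationError("patience must be >= 1")


@dataclass
class CoefficientField:
    """The ``n x p`` matrix of location-specific coefficients ``beta_k(s_i)``."""

    values: np.ndarray
    spot_ids: list[str]
    predictor_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.spot_ids), len(self.predictor_names)):
            raise ValidationError(
                f"field shape {self.values.shape} does not match "
                f"({len(self.spot_ids)}, {len(self.predictor_names)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite coefficients")

    def copy(self) -> "CoefficientField":
        return CoefficientField(
            self.values.copy(), list(self.spot_ids), list(self.predictor_names)
        )


@dataclass
class FitResult:
    field: CoefficientField
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    penalties: PenaltyConfig
    optimizer: OptimizerConfig


def _check_dimensions(dataset: SpatialDataset, values: np.ndarray, H: IncidenceMatrix) -> None:
    n, p = dataset.n_spots, dataset.n_predictors
    if values.shape != (n, p):
        raise ValidationError(f"coefficient matrix must be ({n}, {p}), got {values.shape}")
    if H.n != n:
        raise ValidationError("incidence matrix node count does not match dataset")


def objective_terms(
    dataset: SpatialDataset,
    values: np.ndarray,
    H: IncidenceMatrix,
    penalties: PenaltyConfig,
) -> dict[str, float]:
    """The four objective terms, separately (data, fused, l1, group)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    _check_dimensions(dataset, values, H)
    n = dataset.n_spots
    residual = dataset.response - (dataset.predictors * values).sum(axis=1)
    data = float((residual**2).mean())
    # edgewise gather/difference: O(m p) via the sparse incidence operator
    fused = float(penalties.lambda1 * np.abs(H.matrix @ values).sum())
    l1 = float(penalties.lambda2 * np.abs(values).sum())
    w = penalties.resolve_group_weight(n)
    group = float(penalties.lambda3 * w * np.linalg.norm(values, axis=0).sum())
    return {"data": data, "fused": fused, "l1": l1, "group": group}


def evaluate_objective(
    dataset: SpatialDataset,
    field: CoefficientField | np.ndarray,
    H: IncidenceMatrix,
    penalties: PenaltyConfig,
) -> float:
    """Value of the composite objective at a coefficient field."""
    values = field.values if isinstance(field, CoefficientField) else field
    return sum(objective_terms(dataset, values, H, penalties).values())


def _exact_objective(
    y: np.ndarray, X: np.ndarray, B: np.ndarray, Hs, penalties: PenaltyConfig,
    group_w: float,
) -> float:
    residual = y - (X * B).sum(axis=1)
    obj = float((residual**2).mean())
    obj += penalties.lambda1 * float(np.abs(Hs @ B).sum())
    obj += penalties.lambda2 * float(np.abs(B).sum())
    obj += penalties.lambda3 * group_w * float(np.linalg.norm(B, axis=0).sum())
    return obj


def fit_s3r(
    dataset: SpatialDataset,
    graph: SpatialGraph,
    penalties: PenaltyConfig,
    opt: OptimizerConfig | None = None,
) -> FitResult:
    """Fit the coefficient field by Adam on the smoothed surrogate objective.

    Initialisation is the zero field (the objective is convex, so the optimum
    does not depend on the start).  The surrogate replaces each group norm
    ``||beta_k||_2`` by ``sqrt(||beta_k||^2 + eps)``; L1 and fused terms use
    subgradients with the subgradient at 0 taken as 0.  Training stops at
    ``max_iter`` or when the best objective seen has failed to improve by
    ``tol`` for ``early_stop_patience`` consecutive checks (one check every
    ``check_every`` iterations).  Given one seed and config the trace is
    bit-reproducible.
    """
    if opt is None:
        opt = OptimizerConfig()
    if graph.n_nodes != dataset.n_spots:
        raise ValidationError("graph was not built on this dataset's coordinates")
    H = incidence_matrix(graph)
    Hs = H.matrix
    HsT = Hs.T.tocsr()
    y, X = dataset.response, dataset.predictors
    n, p = dataset.n_spots, dataset.n_predictors
    group_w = penalties.resolve_group_weight(n)
    eps = opt.epsilon_stab
    rng = np.random.default_rng(opt.seed)

    B = np.zeros((n, p))
    m1 = np.zeros_like(B)
    m2 = np.zeros_like(B)
    best_B = B.copy()
    best_obj = _exact_objective(y, X, B, Hs, penalties, group_w)
    trace = [best_obj]
    best_at_check = best_obj
    stall = 0
    converged = False
    t = 0

    for t in range(1, opt.max_iter + 1):
        if opt.batch_mode and opt.batch_size < n:
            rows = rng.choice(n, size=opt.batch_size, replace=False)
        else:
            rows = None

        if rows is None:
            residual = y - (X * B).sum(axis=1)
            grad = -(2.0 / n) * X * residual[:, None]
        else:
            grad = np.zeros_like(B)
            res_b = y[rows] - (X[rows] * B[rows]).sum(axis=1)
            grad[rows] = -(2.0 / len(rows)) * X[rows] * res_b[:, None]
        grad += penalties.lambda1 * (HsT @ np.sign(Hs @ B))
        grad += penalties.lambda2 * np.sign(B)
        norms = np.sqrt((B**2).sum(axis=0) + eps)
        grad += penalties.lambda3 * group_w * B / norms[None, :]

        if opt.grad_clip_norm is not None:
            gnorm = float(np.linalg.norm(grad))
            if gnorm > opt.grad_clip_norm:
                grad *= opt.grad_clip_norm / gnorm

        if opt.schedule == "cosine":
            lr = opt.learning_rate * 0.5 * (1.0 + math.cos(math.pi * (t - 1) / opt.max_iter))
        elif opt.schedule == "step":
            lr = opt.learning_rate * (0.5 ** ((t - 1) // max(1, opt.max_iter // 4)))
        else:
            lr = opt.learning_rate

        m1 = opt.beta1 * m1 + (1 - opt.beta1) * grad
        m2 = opt.beta2 * m2 + (1 - opt.beta2) * grad**2
        m1_hat = m1 / (1 - opt.beta1**t)
        m2_hat = m2 / (1 - opt.beta2**t)
        B = B - lr * m1_hat / (np.sqrt(m2_hat) + opt.adam_eps)

        obj = _exact_objective(y, X, B, Hs, penalties, group_w)
        if not math.isfinite(obj):
            raise DivergenceError(
                "objective became non-finite during training; "
                "try a smaller learning_rate"
            )
        trace.append(obj)
        if obj < best_obj:
            best_obj = obj
            best_B = B.copy()
        # early-stop bookkeeping happens at periodic checks so the initial
        # transient of the adaptive-moment updates cannot abort the run
        if t % opt.check_every == 0:
            if best_obj < best_at_check - opt.tol:
                stall = 0
            else:
                stall += 1
                if stall >= opt.early_stop_patience:
                    converged = True
                    break
            best_at_check = best_obj

    field = CoefficientField(best_B, list(dataset.spot_ids), list(dataset.predictor_names))
    return FitResult(
        field=field,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=t,
        penalties=penalties,
        optimizer=opt,
    )


def hard_threshold(
    field: CoefficientField, threshold: float | None = None
) -> CoefficientField:
    """Set entries with ``|beta| < threshold`` to exactly zero.

    Subgradient methods leave numerically-tiny nonzeros; downstream selection
    and attribution steps need exact zeros.  The default threshold is
    ``1e-6 * max|beta|``.
    """
    if threshold is not None and threshold < 0:
        raise ValidationError("threshold must be nonnegative")
    values = field.values.copy()
    if threshold is None:
        threshold = 1e-6 * float(np.abs(values).max(initial=0.0))
    values[np.abs(values) < threshold] = 0.0
    return CoefficientField(values, list(field.spot_ids), list(field.predictor_names))


def predict(dataset: SpatialDataset, field: CoefficientField) -> np.ndarray:
    """Fitted values ``sum_k x_k(s_i) beta_k(s_i)``."""
    _ = field.values  # validated at construction
    if field.values.shape != dataset.predictors.shape:
        raise ValidationError("field shape does not match dataset")
    return (dataset.predictors * field.values).sum(axis=1)
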