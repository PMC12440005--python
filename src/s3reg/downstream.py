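"""Downstream analyses on fitted coefficient fields.

These are the biological read-outs built on top of the regression core:

* **cell-type attribution** — regressing a gene's spot-level expression on
  deconvolved cell-type proportions gives, per spot, the expression
  attributable to each cell type; biology imposes that contributions are
  non-negative and that an absent cell type contributes nothing;
* **spatially variable gene (SVG) detection** — Moran's I with permutation
  significance on each attributed (gene, cell type) coefficient surface;
* **cross-cell-type covariation** — Spearman correlation across spots between
  attributed fields of two cell types, permutation-tested, FDR-controlled,
  effect-size filtered, and aggregated across sections into a binary
  (gene, gene, cell type, cell type) tensor whose per-pair mean count of
  significant gene pairs is read as a cell–cell interaction strength;
* **context features** — local neighbourhood cell-type composition and
  k-means niches for microenvironment-aware predictor matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata, spearmanr
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .dataset import (
    SpatialDataset,
    ValidationError,
    destandardize_values,
    standardize_dataset,
)
from .graph import SpatialGraph, row_standardized_weights
from .model import (
    CoefficientField,
    OptimizerConfig,
    PenaltyConfig,
    fit_s3r,
    hard_threshold,
)
from .posthoc import apply_selection, cluster_spots, default_n_clusters, refit_and_test


# ---------------------------------------------------------------------------
# cell-type attribution
# ---------------------------------------------------------------------------

@dataclass
class AttributionField:
    """Non-negative per-spot, per-cell-type coefficients for one gene."""

    gene: str
    values: np.ndarray  # n x K
    celltype_names: list[str]
    spot_ids: list[str]
    proportions_ref: np.ndarray  # the n x K proportions used

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValidationError("attribution coefficients must be non-negative")
        if np.any((self.values > 0) & (self.proportions_ref == 0)):
            raise ValidationError(
                "positive attribution where the cell type has zero abundance"
            )


def apply_attribution_constraints(
    values: np.ndarray, proportions: np.ndarray
) -> np.ndarray:
    """Shrink negatives to zero and mask positives where the cell type is absent.

    A cell type can only add to a gene's expression, and cannot contribute at
    spots where its deconvolved abundance is zero.
    """
    values = np.asarray(values, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    if values.shape != proportions.shape:
        raise ValidationError("coefficients and proportions must share shape")
    out = np.where(values < 0, 0.0, values)
    out = np.where(proportions == 0, 0.0, out)
    return out


def attribute_celltypes(
    expression: np.ndarray,
    proportions: np.ndarray,
    coords: np.ndarray,
    graph: SpatialGraph,
    spot_ids: list[str],
    celltype_names: list[str],
    gene: str = "gene",
    penalties: PenaltyConfig | None = None,
    opt: OptimizerConfig | None = None,
    alpha: float = 0.05,
    n_posthoc_clusters: int | None = None,
    seed: int = 0,
) -> AttributionField:
    """Cell-type–attributed expression for one gene.

    Fits the spatial regression of ``expression`` on the proportion columns
    (internally on z-scored predictors with a centred response; coefficients
    are reported on the raw proportion scale), hard-thresholds, runs post-hoc
    cluster-wise significance selection, then applies the attribution
    constraints (non-negativity; zero where the cell type is absent).
    """
    expression = np.asarray(expression, dtype=float).ravel()
    proportions = np.atleast_2d(np.asarray(proportions, dtype=float))
    n, K = proportions.shape
    if K >= n:
        raise ValidationError(
            f"{K} cell types for {n} spots: under-determined even globally"
        )
    if np.any(proportions < 0) or np.any(proportions > 1):
        raise ValidationError("proportions must lie in [0, 1]")
    dataset = SpatialDataset(
        spot_ids=spot_ids,
        coords=coords,
        response=expression,
        predictors=proportions,
        predictor_names=celltype_names,
        section_id=gene,
    )
    # light default shrinkage; for real analyses tune the triple by blocked CV
    penalties = penalties or PenaltyConfig(lambda1=1e-3, lambda2=1e-4, lambda3=1e-4)
    work, info = standardize_dataset(dataset)
    result = fit_s3r(work, graph, penalties, opt)
    raw_field = CoefficientField(
        destandardize_values(result.field.values, info),
        list(result.field.spot_ids),
        list(result.field.predictor_names),
    )
    thresholded = hard_threshold(raw_field)
    n_clusters = n_posthoc_clusters or default_n_clusters(n)
    labels = cluster_spots(coords, n_clusters, seed=seed)
    selection = refit_and_test(dataset, thresholded, labels, alpha=alpha)
    selected = apply_selection(thresholded, selection)
    constrained = apply_attribution_constraints(selected.values, proportions)
    return AttributionField(
        gene=gene,
        values=constrained,
        celltype_names=list(celltype_names),
        spot_ids=list(spot_ids),
        proportions_ref=proportions,
    )


# ---------------------------------------------------------------------------
# Moran's I and SVG detection
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    statistic: float
    perm_pvalue: float
    n_permutations: int
    adjusted_pvalue: float = float("nan")


def morans_i(
    values: np.ndarray,
    graph: SpatialGraph,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I with one-sided permutation significance.

    ``I = (n/S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2)`` with ``z`` the
    centred values and ``W`` the row-standardized binary adjacency of the
    spatial graph (so ``S0 = n``).  The permutation p-value is
    ``(1 + #{I_perm >= I_obs}) / (n_permutations + 1)``, one-sided for
    positive autocorrelation.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n != graph.n_nodes:
        raise ValidationError("values length does not match graph")
    if n_permutations < 99:
        raise ValidationError("need at least 99 permutations")
    z = values - values.mean()
    ss = float((z**2).sum())
    if ss == 0:
        raise ValidationError("Moran's I is undefined for a constant vector")
    W = row_standardized_weights(graph)
    S0 = float(W.sum())
    scale = n / S0
    observed = scale * float(z @ (W @ z)) / ss

    rng = np.random.default_rng(seed)
    Z = rng.permuted(np.broadcast_to(z, (n_permutations, n)), axis=1)
    perm_stats = scale * (Z * (Z @ W.T.tocsr())).sum(axis=1) / ss
    exceed = int((perm_stats >= observed).sum())
    pvalue = (1 + exceed) / (n_permutations + 1)
    return MoranResult(
        statistic=float(observed),
        perm_pvalue=float(pvalue),
        n_permutations=n_permutations,
    )


def detect_svgs(
    attributions: list[AttributionField],
    graph: SpatialGraph,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag spatially variable (gene, cell type) attributed surfaces.

    Each attribution column with at least two distinct values is tested with
    Moran's I; p-values are BH-adjusted jointly across all tested pairs, and
    a pair is an SVG iff its adjusted p is below ``alpha`` and its I is
    positive (spatial structure, not dispersion).
    """
    rows = []
    rng = np.random.default_rng(seed)
    for att in attributions:
        for k, ct in enumerate(att.celltype_names):
            column = att.values[:, k]
            if np.unique(column).size < 2:
                continue
            res = morans_i(
                column, graph, n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {
                    "gene": att.gene,
                    "celltype": ct,
                    "moran_i": res.statistic,
                    "pvalue": res.perm_pvalue,
                    "n_permutations": res.n_permutations,
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene", "celltype", "moran_i", "pvalue", "n_permutations"]
    )
    if len(table):
        _, adj, _, _ = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")
        table["fdr"] = adj
        table["is_svg"] = (table["fdr"] < alpha) & (table["moran_i"] > 0)
    else:
        table["fdr"] = pd.Series(dtype=float)
        table["is_svg"] = pd.Series(dtype=bool)
    return table


# ---------------------------------------------------------------------------
# cross-cell-type covariation
# ---------------------------------------------------------------------------

@dataclass
class CovariationResult:
    section_id: str
    celltype_pair: tuple[str, str]
    gene_pair: tuple[str, str]
    rho: float
    perm_pvalue: float
    fdr: float
    passes_effect_size: bool
    fdr_alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.passes_effect_size and self.fdr < self.fdr_alpha


def _rank_standardize(M: np.ndarray) -> np.ndarray:
    """Column-wise ranks, centred and scaled so that dot products are Spearman rho."""
    R = np.apply_along_axis(rankdata, 0, M)
    R = R - R.mean(axis=0)
    norms = np.sqrt((R**2).sum(axis=0))
    norms[norms == 0] = 1.0
    return R / norms


def covariation_test(
    fieldsA: pd.DataFrame,
    fieldsB: pd.DataFrame,
    celltype_pair: tuple[str, str] = ("C1", "C2"),
    section_id: str = "section",
    n_permutations: int = 999,
    effect_threshold: float = 0.3,
    fdr_alpha: float = 0.05,
    seed: int = 0,
    min_nonzero_spots: int = 3,
) -> list[CovariationResult]:
    """Spearman covariation between two cell types' attributed gene fields.

    ``fieldsA`` / ``fieldsB`` are spots x genes frames of attributed
    coefficients for cell types C1 and C2 sharing the spot axis.  Genes with
    fewer than ``min_nonzero_spots`` nonzero spots in their cell type are
    skipped.  For every remaining (G1, G2), the statistic is the Spearman
    correlation across spots; significance is a two-sided permutation test
    that permutes the spot order of the second field, with BH correction
    across all tested pairs of this cell-type pair; a pair is significant iff
    ``fdr < fdr_alpha`` and ``|rho| >= effect_threshold``.
    """
    if list(fieldsA.index) != list(fieldsB.index):
        raise ValidationError("fields must share the spot axis (same index)")
    n = len(fieldsA)
    keepA = [g for g in fieldsA.columns if (fieldsA[g] != 0).sum() >= min_nonzero_spots]
    keepB = [g for g in fieldsB.columns if (fieldsB[g] != 0).sum() >= min_nonzero_spots]
    if not keepA or not keepB:
        return []
    A = _rank_standardize(fieldsA[keepA].to_numpy(dtype=float))
    B = _rank_standardize(fieldsB[keepB].to_numpy(dtype=float))
    observed = A.T @ B  # gA x gB matrix of Spearman rho

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    abs_obs = np.abs(observed)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        exceed += np.abs(A.T @ B[perm]) >= abs_obs - 1e-12
    pvals = (1.0 + exceed) / (n_permutations + 1)

    flat_p = pvals.ravel()
    _, fdr, _, _ = multipletests(flat_p, method="fdr_bh")
    fdr = fdr.reshape(pvals.shape)

    results = []
    for i, g1 in enumerate(keepA):
        for j, g2 in enumerate(keepB):
            rho = float(observed[i, j])
            results.append(
                CovariationResult(
                    section_id=section_id,
                    celltype_pair=celltype_pair,
                    gene_pair=(g1, g2),
                    rho=rho,
                    perm_pvalue=float(pvals[i, j]),
                    fdr=float(fdr[i, j]),
                    passes_effect_size=abs(rho) >= effect_threshold,
                    fdr_alpha=fdr_alpha,
                )
            )
    return results


def significant_pairs(results: list[CovariationResult]) -> set[tuple]:
    """Canonicalized significant (G1, G2, C1, C2) keys from a result list.

    ``(G1, G2, C1, C2)`` and ``(G2, G1, C2, C1)`` name the same association;
    the canonical key orders the two (gene, cell type) legs lexicographically.
    """
    out = set()
    for r in results:
        if r.significant:
            out.add(canonical_association(r.gene_pair, r.celltype_pair))
    return out


def canonical_association(
    gene_pair: tuple[str, str], celltype_pair: tuple[str, str]
) -> tuple[str, str, str, str]:
    legA = (gene_pair[0], celltype_pair[0])
    legB = (gene_pair[1], celltype_pair[1])
    first, second = sorted([legA, legB])
    return (first[0], second[0], first[1], second[1])


@dataclass
class CovariationTensor:
    """Binary per-section association tensors and their cross-section summary."""

    sections: list[str]
    binary: dict[str, set[tuple]]  # section -> canonical (G1, G2, C1, C2) keys
    replicated: set[tuple]
    aggregated_counts: dict[tuple[str, str], list[int]]  # (C1, C2) -> per-section counts
    interaction_strength: dict[tuple[str, str], float]


def aggregate_tensors(
    section_results: dict[str, set[tuple]],
    min_sections: int = 2,
) -> CovariationTensor:
    """Aggregate per-section significant-pair sets across sections.

    A pair is *replicated* when significant in at least ``min_sections``
    sections.  The interaction strength of a cell-type pair is the arithmetic
    mean, over sections, of its count of significant gene pairs.
    """
    if not section_results:
        raise ValidationError("need at least one section")
    sections = sorted(section_results)
    binary = {s: set(section_results[s]) for s in sections}

    all_keys = set().union(*binary.values()) if binary else set()
    ct_pairs = sorted({(c1, c2) for _, _, c1, c2 in all_keys})

    counts: dict[tuple[str, str], list[int]] = {ct: [] for ct in ct_pairs}
    for s in sections:
        per_ct: dict[tuple[str, str], int] = {ct: 0 for ct in ct_pairs}
        for _, _, c1, c2 in binary[s]:
            per_ct[(c1, c2)] += 1
        for ct in ct_pairs:
            counts[ct].append(per_ct[ct])

    tally: dict[tuple, int] = {}
    for s in sections:
        for key in binary[s]:
            tally[key] = tally.get(key, 0) + 1
    replicated = {key for key, c in tally.items() if c >= min_sections}

    strength = {ct: float(np.mean(counts[ct])) for ct in ct_pairs}
    return CovariationTensor(
        sections=sections,
        binary=binary,
        replicated=replicated,
        aggregated_counts=counts,
        interaction_strength=strength,
    )


# ---------------------------------------------------------------------------
# local-composition context features
# ---------------------------------------------------------------------------

@dataclass
class ContextFeatures:
    local_composition: np.ndarray  # n x T relative frequencies
    celltype_names: list[str]
    niche_labels: np.ndarray  # length-n ints in 0..k_niches-1
    niche_indicators: np.ndarray  # n x k_niches one-hot


def build_context_features(
    coords: np.ndarray,
    celltype_labels,
    k_neighbors: int = 30,
    k_niches: int = 5,
    seed: int = 0,
) -> ContextFeatures:
    """Local neighbourhood composition and mesoscale niches.

    For each cell, the relative cell-type frequencies among its
    ``k_neighbors`` nearest neighbours (Euclidean, self excluded) form a
    local composition vector; k-means with ``k_niches`` clusters on those
    vectors yields niche labels, returned alongside one-hot indicators for
    use as global-context predictors.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray([str(c) for c in celltype_labels])
    n = coords.shape[0]
    if labels.shape != (n,):
        raise ValidationError("cell type labels length does not match coords")
    if not 1 <= k_neighbors < n:
        raise ValidationError(f"k_neighbors must be in [1, {n - 1}]")
    if k_niches < 2:
        raise ValidationError("k_niches must be >= 2")
    types = sorted(str(t) for t in set(labels))
    type_index = {t: j for j, t in enumerate(types)}
    codes = np.array([type_index[t] for t in labels])

    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k_neighbors + 1)
    idx = np.atleast_2d(idx)
    composition = np.zeros((n, len(types)))
    for i in range(n):
        neighbours = [j for j in idx[i] if j != i][:k_neighbors]
        counts = np.bincount(codes[neighbours], minlength=len(types))
        composition[i] = counts / counts.sum()

    km = KMeans(n_clusters=k_niches, n_init=10, random_state=seed)
    niche = km.fit_predict(composition)
    onehot = np.zeros((n, k_niches))
    onehot[np.arange(n), niche] = 1.0
    return ContextFeatures(
        local_composition=composition,
        celltype_names=types,
        niche_labels=niche,
        niche_indicators=onehot,
    )


def spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation between two vectors (convenience wrapper)."""
    rho, _ = spearmanr(a, b)
    return float(rho)
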