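"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written from first principles (enumeration,
dense grids, direct pair counting) and shares no code with the package's own
computational paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def euclid(a, b) -> float:
    return math.dist(a, b)


def brute_force_knn_edges(coords: np.ndarray, k: int) -> set[tuple[int, int]]:
    """All-pairs-distance KNN edge set with smaller-index tie-breaking."""
    n = len(coords)
    edges = set()
    for i in range(n):
        others = sorted(
            (euclid(coords[i], coords[j]), j) for j in range(n) if j != i
        )
        for _, j in others[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges


def enumerate_spanning_trees(n: int, coords: np.ndarray):
    """Yield (total weight, sorted edge tuple) for every spanning tree of K_n."""
    all_edges = list(itertools.combinations(range(n), 2))
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        acyclic = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                acyclic = False
                break
            parent[rj] = ri
        if not acyclic:
            continue
        weight = sum(euclid(coords[i], coords[j]) for i, j in subset)
        yield weight, tuple(sorted(subset))


def min_spanning_tree_weight(coords: np.ndarray) -> float:
    n = len(coords)
    return min(w for w, _ in enumerate_spanning_trees(n, coords))


def pair_counting_ari(a, b) -> float:
    """ARI by direct enumeration of all C(n,2) item pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                ss += 1
            elif same_a:
                sd += 1
            elif same_b:
                ds += 1
            else:
                dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = 0.5 * ((ss + sd) + (ss + ds))
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


def hand_bh(pvalues: list[float], alpha: float) -> list[bool]:
    """Benjamini–Hochberg step-up computed directly from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank * alpha / m:
            k_max = rank
    rejected = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            rejected[idx] = True
    return rejected


def grid_search_objective(
    y: np.ndarray,
    X: np.ndarray,
    H: np.ndarray,
    lambdas: tuple[float, float, float],
    group_weight: float,
    axes: list[np.ndarray],
) -> tuple[np.ndarray, float]:
    """Dense grid minimisation of the composite objective.

    ``axes`` gives the candidate values per coefficient (stacked column-major
    over the n x p field).  Returns (argmin point, min value).  Evaluation is
    vectorised in chunks; the objective is recomputed from its definition and
    shares nothing with the package implementation.
    """
    n, p = X.shape
    l1, l2, l3 = lambdas
    d = len(axes)
    best_val, best_pt = np.inf, None

    def eval_points(pts: np.ndarray) -> np.ndarray:
        B = pts.reshape(-1, n, p, order="F")  # column-major: beta_k stacked
        fitted = (B * X[None, :, :]).sum(axis=2)
        vals = ((y[None, :] - fitted) ** 2).mean(axis=1)
        if H.size:
            diffs = np.einsum("en,bnp->bep", H, B)
            vals = vals + l1 * np.abs(diffs).sum(axis=(1, 2))
        vals = vals + l2 * np.abs(B).sum(axis=(1, 2))
        vals = vals + l3 * group_weight * np.sqrt((B**2).sum(axis=1)).sum(axis=1)
        return vals

    # vectorise the trailing two axes; loop the (small) outer product
    inner = np.stack(
        [g.ravel() for g in np.meshgrid(*axes[max(0, d - 2):], indexing="ij")],
        axis=1,
    )
    outer_axes = axes[: max(0, d - 2)]
    outer_iter = itertools.product(*outer_axes) if outer_axes else [()]
    for prefix in outer_iter:
        pts = np.empty((inner.shape[0], d))
        pts[:, : len(prefix)] = prefix
        pts[:, len(prefix):] = inner
        vals = eval_points(pts)
        i = int(vals.argmin())
        if vals[i] < best_val:
            best_val, best_pt = float(vals[i]), pts[i].copy()
    return best_pt, best_val
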