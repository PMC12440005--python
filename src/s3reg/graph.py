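"""Spatial neighbourhood graphs and their edge–node incidence operator.

The fused (graph) penalty acts on coefficient differences across the edges of
a graph over the spatial locations.  Two constructions are supported:

* a symmetrized k-nearest-neighbour (KNN) graph, the default for small and
  moderate sections, and
* a Euclidean minimum spanning tree (MST), which carries the penalty with
  only ``n - 1`` edges and is the default for large sections.

Both are deterministic: distance ties are broken toward the lexicographically
smaller node pair, so gridded coordinates always yield the same edge set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError, cKDTree

from .dataset import ValidationError

# above this size, KNN queries go through a KD-tree and MST candidates come
# from a Delaunay triangulation instead of the all-pairs distance matrix
_BRUTE_FORCE_LIMIT = 4000


@dataclass
class SpatialGraph:
    """Undirected graph over spatial locations.

    ``edges`` is a list of ``(i, j, weight)`` with ``i < j`` and weight equal
    to the Euclidean distance between the two locations.  An MST has exactly
    ``n_nodes - 1`` edges and is connected by construction.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]
    kind: str

    def __post_init__(self) -> None:
        seen = set()
        for i, j, w in self.edges:
            if i == j:
                raise ValidationError("self-loop in spatial graph")
            if not i < j:
                raise ValidationError("edges must be stored with i < j")
            if (i, j) in seen:
                raise ValidationError(f"duplicate edge ({i}, {j})")
            if w < 0:
                raise ValidationError("negative edge weight")
            seen.add((i, j))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix (weights ignored)."""
        if not self.edges:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        ii = np.array([e[0] for e in self.edges])
        jj = np.array([e[1] for e in self.edges])
        data = np.ones(len(self.edges))
        A = sp.coo_matrix(
            (np.r_[data, data], (np.r_[ii, jj], np.r_[jj, ii])),
            shape=(self.n_nodes, self.n_nodes),
        )
        return A.tocsr()

    def n_components(self) -> int:
        n, _ = sp.csgraph.connected_components(self.adjacency(), directed=False)
        return int(n)


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def build_knn_graph(coords: np.ndarray, k: int) -> SpatialGraph:
    """Symmetrized union-of-neighbours KNN graph.

    Each node contributes edges to its ``k`` nearest neighbours by Euclidean
    distance (ties broken by smaller node index); the union over nodes is the
    undirected edge set, so every node ends with degree >= k.  The graph may
    be disconnected for pathological layouts; callers that need connectivity
    should check :meth:`SpatialGraph.n_components`.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    pairs: set[tuple[int, int]] = set()
    if n <= _BRUTE_FORCE_LIMIT:
        D = _pairwise_distances(coords)
        for i in range(n):
            order = np.lexsort((np.arange(n), D[i]))
            neighbours = [int(j) for j in order if j != i][:k]
            for j in neighbours:
                pairs.add((min(i, j), max(i, j)))
    else:
        tree = cKDTree(coords)
        # query a few extra neighbours so boundary ties can be re-ordered by index
        kq = min(n, k + 4)
        dists, idx = tree.query(coords, k=kq)
        for i in range(n):
            cand = [(float(d), int(j)) for d, j in zip(dists[i], idx[i]) if j != i]
            cand.sort(key=lambda t: (t[0], t[1]))
            for _, j in cand[:k]:
                pairs.add((min(i, j), max(i, j)))
    edges = [
        (i, j, float(np.linalg.norm(coords[i] - coords[j])))
        for i, j in sorted(pairs)
    ]
    return SpatialGraph(n_nodes=n, edges=edges, kind="knn")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _candidate_edges(coords: np.ndarray) -> list[tuple[float, int, int]]:
    n = coords.shape[0]
    if n <= _BRUTE_FORCE_LIMIT:
        D = _pairwise_distances(coords)
        iu, ju = np.triu_indices(n, k=1)
        return list(zip(D[iu, ju].tolist(), iu.tolist(), ju.tolist()))
    try:
        tri = Delaunay(coords)
    except QhullError:
        # degenerate layouts (e.g. collinear points): fall back to all pairs
        D = _pairwise_distances(coords)
        iu, ju = np.triu_indices(n, k=1)
        return list(zip(D[iu, ju].tolist(), iu.tolist(), ju.tolist()))
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                pairs.add((min(i, j), max(i, j)))
    return [
        (float(np.linalg.norm(coords[i] - coords[j])), i, j) for i, j in pairs
    ]


def build_mst(coords: np.ndarray) -> SpatialGraph:
    """Euclidean minimum spanning tree via Kruskal's algorithm.

    Candidate edges are sorted by ``(weight, i, j)``, which makes the tree
    deterministic under exact distance ties (the lexicographically smaller
    node pair wins).  For large inputs candidates are restricted to the
    Delaunay triangulation, which is known to contain the Euclidean MST.
    Duplicate coordinates are allowed and produce zero-weight edges.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValidationError("MST needs at least 2 locations")
    candidates = _candidate_edges(coords)
    candidates.sort()
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for w, i, j in candidates:
        if uf.union(i, j):
            edges.append((int(i), int(j), float(w)))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValidationError("candidate edge set did not span all locations")
    edges.sort(key=lambda e: (e[0], e[1]))
    return SpatialGraph(n_nodes=n, edges=edges, kind="mst")


def build_graph(coords: np.ndarray, kind: str = "auto", k: int = 7,
                auto_threshold: int = 1000) -> SpatialGraph:
    """Dispatch on ``kind``; ``auto`` = KNN up to ``auto_threshold`` spots, MST above."""
    n = np.asarray(coords).shape[0]
    if kind == "auto":
        kind = "knn" if n <= auto_threshold else "mst"
    if kind == "knn":
        return build_knn_graph(coords, k=min(k, n - 1))
    if kind == "mst":
        return build_mst(coords)
    raise ValidationError(f"unknown graph kind {kind!r}")


@dataclass
class IncidenceMatrix:
    """Sparse ``m x n`` edge–node difference operator.

    Row ``r`` corresponds to edge ``r = (i, j)`` of the source graph and has
    ``+1`` at column ``i`` and ``-1`` at column ``j``; applying it to a
    coefficient vector yields the edgewise differences ``beta(s_i) - beta(s_j)``.
    On an MST the operator has full row rank ``n - 1``.
    """

    m: int
    n: int
    matrix: sp.csr_matrix

    def __matmul__(self, other: np.ndarray) -> np.ndarray:
        return self.matrix @ other


def incidence_matrix(graph: SpatialGraph) -> IncidenceMatrix:
    m, n = graph.n_edges, graph.n_nodes
    rows = np.repeat(np.arange(m), 2)
    cols = np.empty(2 * m, dtype=int)
    data = np.empty(2 * m)
    for r, (i, j, _) in enumerate(graph.edges):
        cols[2 * r], cols[2 * r + 1] = i, j
        data[2 * r], data[2 * r + 1] = 1.0, -1.0
    H = sp.coo_matrix((data, (rows, cols)), shape=(m, n)).tocsr()
    return IncidenceMatrix(m=m, n=n, matrix=H)


def row_standardized_weights(graph: SpatialGraph) -> sp.csr_matrix:
    """Row-standardized binary adjacency, the spatial weight matrix W for Moran's I."""
    A = graph.adjacency().astype(float)
    degrees = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(degrees > 0, 1.0 / np.maximum(degrees, 1e-300), 0.0)
    return sp.diags(inv) @ A
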