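"""Distance-based comparison pipelines.

Two classic pipelines serve as baselines for the mixture model: Jaccard
distances between binary sequences, clustered either by complete-linkage
hierarchical clustering or by k-medoids (partitioning around medoids),
with the cluster number selected by the mean silhouette coefficient over
k = 2..20.  Per-cluster marker patterns ("methyltypes") are estimated by
thresholded means (hierarchical) or medoids (k-medoids), and the clone
tree is the minimum spanning tree of the Hamming distances between
methyltypes, rooted at the pattern with the fewest present markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .models import MarkerMatrix

__all__ = ["RootedTree", "BaselineResult", "jaccard_distances",
           "silhouette_select", "estimate_methyltypes", "hamming_mst",
           "run_baseline"]

METHODS = ("hierarchical", "k_centroids")


@dataclass(frozen=True)
class RootedTree:
    """Spanning tree over clusters, directed away from the root."""

    n_nodes: int
    root: int
    edges: tuple  # (parent, child) pairs, indices into the methyltypes


@dataclass(frozen=True)
class BaselineResult:
    labels: np.ndarray       # cluster id per observation, 1..k
    methyltypes: np.ndarray  # k x M binary patterns
    tree: RootedTree
    k: int
    silhouette: float


def jaccard_distances(X: MarkerMatrix) -> np.ndarray:
    """Pairwise Jaccard distances between the rows of a complete matrix.

    ``d(a, b)`` is the fraction of sites where exactly one row is 1
    among the sites where at least one is; two all-zero rows are at
    distance 0 (empty-union convention).
    """
    if X.missing_mask.any():
        raise ValueError("baselines require a complete matrix (no missing)")
    B = X.values.astype(bool)
    return squareform(pdist(B, metric="jaccard"))


def _kmedoids(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids on a precomputed distance matrix.

    Greedy BUILD initialization followed by Voronoi iterations
    (reassign to nearest medoid, recompute each cluster's medoid); ties
    break toward the lower index.  Returns labels 1..k.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size:
                within = D[np.ix_(members, members)].sum(axis=0)
                new[c] = members[int(np.argmin(within))]
        new = np.sort(new)
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(D[:, medoids], axis=1) + 1
    return labels, medoids


def silhouette_select(D: np.ndarray, method: str = "hierarchical",
                      k_max: int = 20) -> tuple:
    """Pick the cluster number (2..k_max) maximizing mean silhouette.

    ``hierarchical`` cuts a complete-linkage agglomeration of ``D``;
    ``k_centroids`` runs partitioning-around-medoids on ``D``.  Returns
    ``(k, labels, silhouette)``.  Degenerate input (all rows identical)
    yields a single cluster with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for model selection")
    if not D[np.triu_indices(n, 1)].any():
        warnings.warn("all observations identical; returning one cluster")
        return 1, np.ones(n, dtype=int), 0.0
    if method == "hierarchical":
        Z = linkage(squareform(D, checks=False), method="complete")
    best = (-np.inf, None, None)
    for k in range(2, min(k_max, n - 1) + 1):
        if method == "hierarchical":
            labels = fcluster(Z, k, criterion="maxclust")
        else:
            labels, _ = _kmedoids(D, k)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed")
        if score > best[0]:
            best = (score, k, labels)
    score, k, labels = best
    # relabel to a dense 1..k in first-appearance order
    _, dense = np.unique(labels, return_inverse=True)
    return k, dense + 1, float(score)


def estimate_methyltypes(X: MarkerMatrix, labels: np.ndarray,
                         method: str = "hierarchical") -> np.ndarray:
    """Per-cluster binary patterns.

    Hierarchical: site-wise mean strictly above 0.5 maps to 1 (a tied
    mean maps to 0).  k-centroids: the medoid row of the cluster under
    Jaccard distance.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    labels = np.asarray(labels)
    ks = np.unique(labels)
    out = np.zeros((len(ks), X.n_sites), dtype=np.int8)
    D = jaccard_distances(X) if method == "k_centroids" else None
    for row, k in enumerate(ks):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            raise ValueError(f"cluster {k} is empty")
        if method == "hierarchical":
            out[row] = (X.values[members].mean(axis=0) > 0.5).astype(np.int8)
        else:
            within = D[np.ix_(members, members)].sum(axis=0)
            out[row] = X.values[members[int(np.argmin(within))]]
    return out


def hamming_mst(methyltypes: np.ndarray) -> RootedTree:
    """Minimum spanning tree of pairwise Hamming distances.

    Stable Kruskal with lexicographic (weight, i, j) edge ordering; the
    root is the pattern with the fewest 1s (ties: lexicographically
    smallest pattern), and edges are directed away from it.
    """
    G = np.asarray(methyltypes, dtype=np.int8)
    k = G.shape[0]
    if k == 0:
        raise ValueError("need at least one methyltype")
    if k == 1:
        return RootedTree(n_nodes=1, root=0, edges=())
    edges = sorted((int((G[i] != G[j]).sum()), i, j)
                   for i in range(k) for j in range(i + 1, k))
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    picked = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            picked.append((i, j))
            if len(picked) == k - 1:
                break
    root = min(range(k), key=lambda i: (int(G[i].sum()), tuple(G[i])))
    adj = {i: [] for i in range(k)}
    for i, j in picked:
        adj[i].append(j)
        adj[j].append(i)
    directed, seen, stack = [], {root}, [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                directed.append((u, v))
                stack.append(v)
    return RootedTree(n_nodes=k, root=root, edges=tuple(directed))


def run_baseline(X: MarkerMatrix, method: str = "hierarchical",
                 k_max: int = 20) -> BaselineResult:
    """Full pipeline: distances, model selection, methyltypes, tree."""
    D = jaccard_distances(X)
    k, labels, score = silhouette_select(D, method=method, k_max=k_max)
    methyltypes = estimate_methyltypes(X, labels, method=method)
    tree = hamming_mst(methyltypes)
    return BaselineResult(labels=labels, methyltypes=methyltypes,
                          tree=tree, k=k, silhouette=score)
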