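"""Functional-similarity clustering of synergies across subjects.

Synergies (of one mode, temporal or spatial, never mixed) are compared by
the Pearson correlation of their vectorized full-movement confusion
matrices: two synergies are functionally similar when they make the same
task distinctions, regardless of their activation shape.  Clusters are
formed by complete-linkage agglomeration on distance 1 - r with a cutoff;
singleton components are labelled unclustered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Distance assigned to pairs whose correlation is undefined (degenerate
#: confusion matrices); beyond the 1 - r maximum of 2 so such synergies
#: end up as singletons.
MISSING_DISTANCE = 2.0


@dataclass
class FunctionalSimilarityMatrix:
    """Pairwise confusion-matrix correlations with a synergy registry.

    ``r`` is symmetric with unit diagonal; undefined entries are NaN.
    ``registry`` carries one row per synergy (subject, synergy index,
    mode) in matrix order.
    """

    r: np.ndarray
    registry: pd.DataFrame = field(repr=False)

    @property
    def n(self) -> int:
        return self.r.shape[0]

    def distances(self, missing: float = MISSING_DISTANCE) -> np.ndarray:
        """1 - r with NaN imputed as ``missing`` and a zero diagonal."""
        d = 1.0 - self.r
        d[np.isnan(d)] = missing
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ClusterSet:
    """Cluster assignments after cutting the tree.

    ``assignments[i]`` is the cluster id of synergy i, or -1 when the
    synergy ended up as a singleton (unclustered).
    """

    assignments: np.ndarray
    tree: np.ndarray
    cutoff: float

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignments.tolist()) - {-1})

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster_id)


@dataclass
class ClusterSummary:
    """Averaged representatives of one cluster."""

    cluster_id: int
    member_indices: np.ndarray
    mean_synergy: np.ndarray
    sem_synergy: np.ndarray
    mean_confusion: np.ndarray


def functional_similarity_matrix(
    confusions: list[np.ndarray], registry: pd.DataFrame | None = None
) -> FunctionalSimilarityMatrix:
    """Pearson correlation of vectorized confusion matrices for every pair.

    All matrices must share the class set and ordering (a V-class matrix
    vectorizes to V*V elements, 5184 for the 72-movement set).  Pairs
    involving a zero-variance vector get NaN.
    """
    if len(confusions) < 1:
        raise ValueError("need at least one confusion matrix")
    shape = np.asarray(confusions[0]).shape
    vecs = []
    for D in confusions:
        D = np.asarray(D, dtype=float)
        if D.shape != shape:
            raise ValueError("all confusion matrices must share shape and class order")
        vecs.append(D.ravel())
    V = np.stack(vecs)
    std = V.std(axis=1)
    n = V.shape[0]
    r = np.full((n, n), np.nan)
    ok = std > 0
    if ok.any():
        sub = np.corrcoef(V[ok])
        if ok.sum() == 1:
            sub = np.array([[1.0]])
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, 1.0)
    if registry is None:
        registry = pd.DataFrame(
            {"subject": 0, "synergy": np.arange(n), "mode": "unknown"}
        )
    if len(registry) != n:
        raise ValueError("registry must have one row per confusion matrix")
    return FunctionalSimilarityMatrix(r=r, registry=registry.reset_index(drop=True))


def build_tree(sim, linkage: str = "complete") -> np.ndarray:
    """Complete-linkage agglomerative merge tree on distance 1 - r.

    Accepts a FunctionalSimilarityMatrix or a square distance matrix.
    Returns an (n-1, 4) merge table in scipy linkage layout: each row is
    (id_a, id_b, height, size) with new clusters numbered n, n+1, ...
    Ties are broken deterministically toward the lowest (i, j) pair.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    if isinstance(sim, FunctionalSimilarityMatrix):
        D = sim.distances()
    else:
        D = np.asarray(sim, dtype=float).copy()
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 synergies to build a tree")

    active = {i: i for i in range(n)}  # position -> cluster id
    sizes = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    positions = list(range(n))
    for step in range(n - 1):
        best = None
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                d = D[i, j]
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        ci, cj = active[i], active[j]
        a, b = min(ci, cj), max(ci, cj)
        Z[step] = (a, b, d, sizes[ci] + sizes[cj])
        # complete linkage: distance to the merged cluster is the max
        for k in positions:
            if k not in (i, j):
                D[i, k] = D[k, i] = max(D[i, k], D[j, k])
        positions.remove(j)
        active[i] = next_id
        sizes[next_id] = sizes[ci] + sizes[cj]
        next_id += 1
    return Z


def cut_tree(tree: np.ndarray, cutoff: float, n: int | None = None) -> np.ndarray:
    """Flat clusters from merges at height <= cutoff; singletons become -1."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = np.asarray(tree, dtype=float)
    n = int(tree.shape[0] + 1) if n is None else n
    parent = list(range(n + tree.shape[0]))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, height, _) in enumerate(tree):
        node = n + step
        if height <= cutoff:
            parent[find(int(a))] = node
            parent[find(int(b))] = node

    roots = [find(i) for i in range(n)]
    counts: dict[int, int] = {}
    for root in roots:
        counts[root] = counts.get(root, 0) + 1
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    seen: dict[int, int] = {}
    for i, root in enumerate(roots):
        if counts[root] < 2:
            continue
        if root not in seen:
            seen[root] = next_label
            next_label += 1
        labels[i] = seen[root]
    if next_label == 0:
        warnings.warn("cutoff below all merge heights: everything unclustered",
                      stacklevel=2)
    return labels


def cut_and_summarize(
    tree: np.ndarray,
    cutoff: float,
    synergies: list[np.ndarray],
    confusions: list[np.ndarray],
) -> tuple[ClusterSet, list[ClusterSummary]]:
    """Cut the tree and average each cluster's synergies and confusion matrices.

    Synergy profiles are averaged member-wise (assumed already under the
    unit-norm convention); confusion matrices are averaged entrywise and
    then row-renormalized.
    """
    labels = cut_tree(tree, cutoff, n=len(synergies))
    cluster_set = ClusterSet(assignments=labels, tree=np.asarray(tree), cutoff=cutoff)
    summaries = []
    for cid in cluster_set.cluster_ids:
        members = cluster_set.members(cid)
        syn = np.stack([np.asarray(synergies[i], dtype=float) for i in members])
        conf = np.stack([np.asarray(confusions[i], dtype=float) for i in members])
        mean_conf = conf.mean(axis=0)
        rows = mean_conf.sum(axis=1, keepdims=True)
        mean_conf = np.divide(
            mean_conf, rows, out=np.zeros_like(mean_conf), where=rows > 0
        )
        summaries.append(
            ClusterSummary(
                cluster_id=cid,
                member_indices=members,
                mean_synergy=syn.mean(axis=0),
                sem_synergy=syn.std(axis=0, ddof=1) / np.sqrt(len(members)),
                mean_confusion=mean_conf,
            )
        )
    return cluster_set, summaries
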