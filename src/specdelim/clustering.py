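"""F-linkage clustering of a distance matrix.

A *link* is a pairwise distance d <= T. An object (or cluster) may join a
cluster when at least a fraction F of the distances between the two groups
are links: F=0 behaves as single linkage (one link suffices), F=1 as
complete linkage (all distances must be links), and intermediate F
interpolates between the two.

The merge schedule is greedy best-first agglomeration: starting from
singletons, repeatedly merge the pair of clusters with the largest link
fraction among all mergeable pairs (a pair is mergeable when its link
fraction reaches F *and* it has at least one link — the one-link floor makes
F=0 exactly single linkage). Ties are broken by the smallest mean
inter-cluster distance, then by the lexicographically smallest member
labels, so the result is deterministic and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ClusteringError
from .io_formats import DistanceMatrix, Partition

__all__ = ["ClusteringParams", "f_linkage_cluster", "cluster_link_matrix"]


@dataclass(frozen=True)
class ClusteringParams:
    """Threshold T and required link fraction F, both in [0, 1]."""

    T: float
    F: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.T <= 1.0:
            raise ClusteringError(f"T must be in [0, 1], got {self.T}")
        if not 0.0 <= self.F <= 1.0:
            raise ClusteringError(f"F must be in [0, 1], got {self.F}")


@njit(cache=True)
def _greedy_merge(d, link, F, rank):  # pragma: no cover - exercised via wrapper
    """Greedy best-first F-linkage agglomeration.

    d     : (n, n) float64 distance matrix
    link  : (n, n) float64 0/1 link indicator
    F     : required link fraction
    rank  : (n,) int64 lexicographic rank of each object's label (tie-break)

    Returns an (n,) int64 membership array (values are representative
    object indices, not normalized).
    """
    n = d.shape[0]
    C = link.copy()          # link counts between clusters
    S = d.copy()             # summed distances between clusters
    size = np.ones(n, dtype=np.float64)
    minrank = rank.copy()
    active = np.ones(n, dtype=np.bool_)
    memb = np.arange(n)
    while True:
        bi = -1
        bj = -1
        bL = -1.0
        bmean = 1e300
        br1 = np.int64(2**62)
        br2 = np.int64(2**62)
        for i in range(n):
            if not active[i]:
                continue
            for j in range(i + 1, n):
                if not active[j]:
                    continue
                cnt = C[i, j]
                if cnt < 0.5:  # one-link floor
                    continue
                prod = size[i] * size[j]
                L = cnt / prod
                if L + 1e-12 < F:
                    continue
                mean = S[i, j] / prod
                if minrank[i] < minrank[j]:
                    r1, r2 = minrank[i], minrank[j]
                else:
                    r1, r2 = minrank[j], minrank[i]
                take = False
                if L > bL + 1e-12:
                    take = True
                elif L > bL - 1e-12:
                    if mean < bmean - 1e-15:
                        take = True
                    elif mean < bmean + 1e-15:
                        if r1 < br1 or (r1 == br1 and r2 < br2):
                            take = True
                if take:
                    bi, bj, bL, bmean, br1, br2 = i, j, L, mean, r1, r2
        if bi < 0:
            break
        # merge bj into bi
        for k in range(n):
            if active[k] and k != bi and k != bj:
                C[bi, k] += C[bj, k]
                C[k, bi] = C[bi, k]
                S[bi, k] += S[bj, k]
                S[k, bi] = S[bi, k]
        size[bi] += size[bj]
        if minrank[bj] < minrank[bi]:
            minrank[bi] = minrank[bj]
        active[bj] = False
        for o in range(n):
            if memb[o] == bj:
                memb[o] = bi
    return memb


def _membership_to_partition(labels: list[str], memb: np.ndarray) -> Partition:
    """Number clusters 0..k-1 by order of their lexicographically smallest member."""
    groups: dict[int, list[str]] = {}
    for lab, m in zip(labels, memb):
        groups.setdefault(int(m), []).append(lab)
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    return Partition({lab: str(k) for k, ms in enumerate(ordered) for lab in ms})


def cluster_link_matrix(
    matrix: DistanceMatrix, link: np.ndarray, F: float
) -> Partition:
    """Cluster with an explicit 0/1 link matrix (the T-interval fast path)."""
    order = np.argsort(np.array(matrix.labels))
    rank = np.empty(len(matrix.labels), dtype=np.int64)
    rank[order] = np.arange(len(matrix.labels))
    memb = _greedy_merge(
        matrix.values.astype(np.float64),
        link.astype(np.float64),
        float(F),
        rank,
    )
    return _membership_to_partition(matrix.labels, memb)


def f_linkage_cluster(matrix: DistanceMatrix, params: ClusteringParams) -> Partition:
    """Partition the matrix's objects by F-linkage clustering at (T, F).

    Deterministic for fixed input. Cluster labels are "0".."k-1", numbered
    by the order of each cluster's lexicographically smallest member (the
    numbers are arbitrary identifiers and imply no relatedness).
    """
    if len(matrix) == 0:
        raise ClusteringError("empty distance matrix")
    link = (matrix.values <= params.T).astype(np.float64)
    np.fill_diagonal(link, 0.0)
    return cluster_link_matrix(matrix, link, params.F)
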