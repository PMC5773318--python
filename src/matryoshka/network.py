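"""Shared-allele distance (DAS) and minimum spanning tree.

DAS between two individuals is 1 minus the proportion of alleles they
share over co-typed loci, with the shared count at a locus defined as the
multiset intersection of the two allele pairs (A/A vs A/B share 1, not
2).  Pairs with no co-typed locus are NA.  The MST uses Kruskal's
algorithm with deterministic (distance, i, j) tie-breaking; NA blocks
yield a spanning forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DasMatrix:
    values: np.ndarray  # N x N in [0,1], NaN where undefined
    co_typed: np.ndarray  # N x N count of co-typed loci
    individual_ids: list[str]


@dataclass
class MstEdges:
    edges: list[tuple[int, int, float]]
    n_components: int
    individual_ids: list[str]

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.individual_ids[i], self.individual_ids[j], w)
                for i, j, w in self.edges
            ],
            columns=["id_i", "id_j", "das"],
        )


def das_matrix(gm: GenotypeMatrix) -> DasMatrix:
    """Pairwise shared-allele distance D_AS = 1 - sum_l shared_l / (2 L')."""
    if gm.n_individuals < 2:
        raise ValueError("need at least two individuals")
    a1 = gm.alleles[:, :, 0].astype(np.int64)
    a2 = gm.alleles[:, :, 1].astype(np.int64)
    typed = ~gm.missing_mask
    N = gm.n_individuals
    D = np.zeros((N, N))
    C = np.zeros((N, N), dtype=np.int64)
    for i in range(N):
        shared = np.maximum(
            (a1[i] == a1).astype(np.int64) + (a2[i] == a2),
            (a1[i] == a2).astype(np.int64) + (a2[i] == a1),
        )
        ok = typed[i] & typed
        lprime = ok.sum(axis=1)
        s = np.where(ok, shared, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = 1.0 - s / (2.0 * lprime)
        D[i, lprime == 0] = np.nan
        C[i] = lprime
    np.fill_diagonal(D, 0.0)
    if np.isnan(D[np.triu_indices(N, 1)]).any():
        logger.warning("some pairs share no co-typed locus: DAS undefined (NA)")
    return DasMatrix(D, C, list(gm.individual_ids))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(d: DasMatrix) -> MstEdges:
    """Kruskal MST on the DAS matrix; disconnected NA blocks yield a forest."""
    n = d.values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = d.values[iu, ju]
    ok = np.isfinite(w)
    if not ok.any():
        raise ValueError("no finite off-diagonal distance")
    order = np.lexsort((ju[ok], iu[ok], w[ok]))  # ties: distance, then (i, j)
    iu, ju, w = iu[ok][order], ju[ok][order], w[ok][order]
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for i, j, dist in zip(iu, ju, w):
        if uf.union(int(i), int(j)):
            edges.append((int(i), int(j), float(dist)))
            if len(edges) == n - 1:
                break
    n_components = len({uf.find(i) for i in range(n)})
    return MstEdges(edges, n_components, list(d.individual_ids))


def cross_cluster_edge_fraction(mst: MstEdges, labels: np.ndarray) -> float:
    """Fraction of MST edges joining individuals from different clusters."""
    if not mst.edges:
        return np.nan
    cross = sum(1 for i, j, _ in mst.edges if labels[i] != labels[j])
    return cross / len(mst.edges)
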