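"""Multilocus genotype (MLG) identification — clonemate screening.

Two matching policies are supported.  Under ``strict`` two individuals are
clonemates iff neither has any missing locus and their genotypes agree at
every locus (allele pairs compared as unordered multisets; heterozygote
phase carries no information for microsatellites).  Under ``tolerant``
they match iff they agree at every locus typed in both and share at least
one typed locus; groups are the transitive closure of that relation, which
can chain individuals that were never directly compared — a warning is
logged when the closure merges such pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class MlgPartition:
    """Partition of individuals into multilocus genotypes."""

    assignment: dict[str, int]  # individual id -> MLG id
    sizes: dict[int, int]
    representatives: dict[int, str]  # MLG id -> first individual by input order
    unassignable: list[str]  # all-missing individuals under tolerant policy

    @property
    def n_mlg(self) -> int:
        return len(self.sizes)

    def labels(self, individual_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in individual_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": list(self.assignment),
                "mlg_id": [self.assignment[i] for i in self.assignment],
                "mlg_size": [self.sizes[self.assignment[i]] for i in self.assignment],
            }
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _match(sorted_alleles: np.ndarray, miss: np.ndarray, i: int, j: int, policy: str) -> bool:
    if policy == "strict":
        if miss[i].any() or miss[j].any():
            return False
        return bool((sorted_alleles[i] == sorted_alleles[j]).all())
    shared = ~miss[i] & ~miss[j]
    if not shared.any():
        return False
    return bool((sorted_alleles[i][shared] == sorted_alleles[j][shared]).all())


def identify_mlg(gm: GenotypeMatrix, policy: str = "strict") -> MlgPartition:
    """Group individuals into MLGs under the given matching ``policy``.

    Default is strict (an individual with any missing locus is its own
    MLG), the conservative choice when screening for clonality.
    """
    if policy not in ("strict", "tolerant"):
        raise ValueError("policy must be 'strict' or 'tolerant'")
    n = gm.n_individuals
    srt = np.sort(gm.alleles, axis=2)
    srt = np.where(gm.missing_mask[:, :, None], 0, srt)
    miss = gm.missing_mask
    uf = _UnionFind(n)
    unassignable = []

    if policy == "strict":
        # hashable key per fully typed individual: exact grouping in O(N)
        buckets: dict[bytes, int] = {}
        for i in range(n):
            if miss[i].any():
                continue
            key = srt[i].tobytes()
            if key in buckets:
                uf.union(buckets[key], i)
            else:
                buckets[key] = i
    else:
        for i in range(n):
            if miss[i].all():
                unassignable.append(gm.individual_ids[i])
                continue
            for j in range(i + 1, n):
                if uf.find(i) == uf.find(j):
                    continue
                if _match(srt, miss, i, j, policy):
                    uf.union(i, j)
        _warn_on_chained_merges(srt, miss, uf, n)

    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    sizes: dict[int, int] = {}
    reps: dict[int, str] = {}
    for i in range(n):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots)
            reps[roots[r]] = gm.individual_ids[i]
            sizes[roots[r]] = 0
        mlg = roots[r]
        assignment[gm.individual_ids[i]] = mlg
        sizes[mlg] += 1
    return MlgPartition(assignment, sizes, reps, unassignable)


def _warn_on_chained_merges(srt, miss, uf: _UnionFind, n: int) -> None:
    """Tolerant closure can join pairs with no shared typed locus; flag them."""
    chained = 0
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j) and not (~miss[i] & ~miss[j]).any():
                chained += 1
    if chained:
        logger.warning(
            "tolerant closure merged %d pairs sharing no typed locus", chained
        )


def reduce_to_mlg(gm: GenotypeMatrix, partition: MlgPartition) -> GenotypeMatrix:
    """Keep one representative (first by input order) per MLG."""
    keep = {partition.representatives[m] for m in partition.representatives}
    idx = [i for i, ind in enumerate(gm.individual_ids) if ind in keep]
    return gm.subset(idx)
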