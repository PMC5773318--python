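"""Synthetic diploid microsatellite genotypes with nested population structure.

The generator emulates a two-level "Russian-doll" design: ancestral allele
frequencies drift into top-level lineages, which drift further into nested
clusters (multiallelic Balding-Nichols, i.e. Dirichlet drift — exactly the
correlated-allele-frequency prior of the Bayesian clustering model, so
parameter-recovery tests are a fair comparison of like with like).
Individuals are drawn in Hardy-Weinberg proportions from their cluster's
frequencies; sampling sites are pure mixture containers with no site-level
drift, so distinct clusters co-occur (sympatry) at every site.  On top of
that, rare admixed individuals (gene-by-gene mixtures of two sibling
clusters) and rare F2 hybrids are spiked in, and genotypes are masked
missing completely at random.

Everything is deterministic under the config seed and a full ground-truth
record (:class:`SimTruth`) is returned alongside the genotypes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, SampleHierarchy

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    Defaults reproduce the structure the pipeline is built to detect:
    three lineages (drift ``F_level1`` from the ancestor) splitting into
    {3, 2, 3} clusters (drift ``F_level2`` from each lineage), 13 loci with
    ~14 alleles each, eight sites each receiving a uniform mixture of all
    clusters (150 individuals/site -> expected 150/cluster), 5% missing
    data, 6% admixed individuals and 0.7% F2 hybrids.
    """

    seed: int = 0
    L: int = 13
    alleles_per_locus: int = 14
    tree_spec: tuple[int, ...] = (3, 2, 3)  # clusters per lineage
    F_level1: float = 0.20
    F_level2: float = 0.12
    n_sites: int = 8
    n_per_site: int = 150
    site_mixtures: np.ndarray | None = None  # n_sites x n_clusters proportions
    missing_rate: float = 0.05
    admixed_fraction: float = 0.06
    hybrid_fraction: float = 0.007

    def __post_init__(self) -> None:
        if not (0 < self.F_level1 < 1 and 0 < self.F_level2 < 1):
            raise ValueError("drift parameters must lie in (0, 1)")
        if self.admixed_fraction + self.hybrid_fraction > 1:
            raise ValueError("special-individual fractions must sum to <= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if min(self.L, self.alleles_per_locus, self.n_sites, self.n_per_site) < 1:
            raise ValueError("counts must be positive")
        if any(c < 1 for c in self.tree_spec):
            raise ValueError("each lineage needs at least one cluster")

    @property
    def n_lineages(self) -> int:
        return len(self.tree_spec)

    @property
    def n_clusters(self) -> int:
        return int(sum(self.tree_spec))

    def cluster_lineage(self) -> np.ndarray:
        """Lineage index of each flat cluster index."""
        return np.repeat(np.arange(self.n_lineages), self.tree_spec)


@dataclass
class SimTruth:
    """Ground-truth record for a simulated dataset."""

    lineage: np.ndarray  # per-individual lineage index
    cluster: np.ndarray  # per-individual cluster index (flat)
    kind: np.ndarray  # 'pure' | 'admixed' | 'f2'
    q_true: dict[int, np.ndarray] = field(default_factory=dict)  # admixed: cluster->weight over clusters
    hybrid_parents: dict[int, tuple[int, int]] = field(default_factory=dict)
    pi: np.ndarray | None = None  # L x A ancestral frequencies
    p_lineage: np.ndarray | None = None  # n_lineages x L x A
    p_cluster: np.ndarray | None = None  # n_clusters x L x A
    realized_missing_rate: float = 0.0

    def to_json(self) -> str:
        payload = {
            "lineage": self.lineage.tolist(),
            "cluster": self.cluster.tolist(),
            "kind": self.kind.tolist(),
            "q_true": {str(k): v.tolist() for k, v in self.q_true.items()},
            "hybrid_parents": {str(k): list(v) for k, v in self.hybrid_parents.items()},
            "realized_missing_rate": self.realized_missing_rate,
        }
        return json.dumps(payload, indent=1)


def _dirichlet_drift(rng: np.random.Generator, base: np.ndarray, F: float) -> np.ndarray:
    """One Balding-Nichols drift step: Dirichlet(base * (1-F)/F)."""
    conc = base * (1.0 - F) / F
    if conc.min() < 1e-7:
        raise ValueError(
            "Dirichlet concentration underflow: F too close to 1 for rare alleles"
        )
    out = rng.dirichlet(conc)
    # floor rare alleles so repeated drift steps stay numerically valid
    out = np.maximum(out, 1e-5)
    return out / out.sum()


def simulate_hierarchy(config: SimConfig):
    """Simulate genotypes; returns ``(GenotypeMatrix, SampleHierarchy, SimTruth)``.

    Missing data and special individuals (admixed, F2) are applied
    according to the config; pass fractions/rate of 0 to disable.
    """
    rng = np.random.default_rng(config.seed)
    L, A = config.L, config.alleles_per_locus
    nclus = config.n_clusters

    pi = np.stack([_dirichlet_drift(rng, np.ones(A), 0.5) for _ in range(L)])
    # pi ~ symmetric Dirichlet(1): drift step from ones with F=0.5 gives conc 1
    p_lin = np.stack(
        [
            np.stack([_dirichlet_drift(rng, pi[l], config.F_level1) for l in range(L)])
            for _ in range(config.n_lineages)
        ]
    )
    lin_of = config.cluster_lineage()
    p_clus = np.stack(
        [
            np.stack([_dirichlet_drift(rng, p_lin[lin_of[c], l], config.F_level2) for l in range(L)])
            for c in range(nclus)
        ]
    )

    if config.site_mixtures is None:
        mix = np.full((config.n_sites, nclus), 1.0 / nclus)
    else:
        mix = np.asarray(config.site_mixtures, dtype=float)
        if mix.shape != (config.n_sites, nclus):
            raise ValueError("site_mixtures must be n_sites x n_clusters")
        mix = mix / mix.sum(axis=1, keepdims=True)

    n_total = config.n_sites * config.n_per_site
    cluster = np.empty(n_total, dtype=np.int64)
    sites: list[str] = []
    for s in range(config.n_sites):
        lo = s * config.n_per_site
        cluster[lo : lo + config.n_per_site] = rng.choice(
            nclus, size=config.n_per_site, p=mix[s]
        )
        sites.extend([f"site{s + 1}"] * config.n_per_site)

    alleles = np.empty((n_total, L, 2), dtype=np.int32)
    for c in range(nclus):
        rows = np.where(cluster == c)[0]
        for l in range(L):
            draws = rng.choice(A, size=(rows.size, 2), p=p_clus[c, l])
            alleles[rows, l] = draws + 1  # codes 1..A

    truth = SimTruth(
        lineage=lin_of[cluster].copy(),
        cluster=cluster,
        kind=np.array(["pure"] * n_total, dtype=object),
        pi=pi,
        p_lineage=p_lin,
        p_cluster=p_clus,
    )
    hier = SampleHierarchy(
        sites,
        island=[f"island{(int(s[4:]) - 1) // 2 + 1}" for s in sites],
        ecoregion=[f"ecoregion{(int(s[4:]) - 1) // 4 + 1}" for s in sites],
        province=["province1"] * n_total,
    )
    ids = [f"ind{i + 1:05d}" for i in range(n_total)]
    gm = GenotypeMatrix(ids, [f"locus{l + 1:02d}" for l in range(L)], alleles)

    gm, truth = spike_special_individuals(
        gm, truth, config.admixed_fraction, config.hybrid_fraction,
        int(rng.integers(2**31)), p_cluster=p_clus, tree_spec=config.tree_spec,
    )
    gm = inject_missing(gm, config.missing_rate, int(rng.integers(2**31)))
    truth.realized_missing_rate = float(gm.missing_mask.mean())
    return gm, hier, truth


def inject_missing(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask each (individual, locus) cell missing with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0:
        return gm
    if rate > 0.9:
        logger.warning("missing rate %.2f leaves almost no data", rate)
    rng = np.random.default_rng(seed)
    mask = gm.missing_mask | (rng.random(gm.missing_mask.shape) < rate)
    alleles = np.where(mask[:, :, None], 0, gm.alleles)
    return GenotypeMatrix(list(gm.individual_ids), list(gm.locus_names), alleles, mask)


def _sibling_pairs(tree_spec) -> list[tuple[int, int]]:
    """All unordered pairs of clusters sharing a lineage (fallback: any pair)."""
    offsets = np.concatenate([[0], np.cumsum(tree_spec)])
    pairs = []
    for g, k in enumerate(tree_spec):
        ids = range(int(offsets[g]), int(offsets[g + 1]))
        pairs.extend((a, b) for a in ids for b in ids if a < b)
    if not pairs:  # no lineage has two clusters: pair across lineages
        n = int(offsets[-1])
        pairs = [(a, b) for a in range(n) for b in range(n) if a < b]
    return pairs


def spike_special_individuals(
    gm: GenotypeMatrix,
    truth: SimTruth,
    admixed_fraction: float,
    hybrid_fraction: float,
    seed: int,
    *,
    p_cluster: np.ndarray | None = None,
    tree_spec=None,
):
    """Overwrite a random subset of individuals with admixed / F2 genotypes.

    Admixed individuals are gene-by-gene mixtures of two sibling clusters
    with weights ``q_true ~ Dirichlet(1, 1)``; F2 hybrids draw each locus's
    gene-origin pair from the (1/4, 1/2, 1/4) law over
    (p1,p1)/(p1,p2)/(p2,p2).  Fractions above 0.5 are refused — the
    downstream rarity assumptions would no longer hold.
    """
    if admixed_fraction == 0 and hybrid_fraction == 0:
        return gm, truth
    if admixed_fraction > 0.5 or hybrid_fraction > 0.5:
        raise ValueError("special-individual fractions above 0.5 are not supported")
    if p_cluster is None:
        p_cluster = truth.p_cluster
    if p_cluster is None:
        raise ValueError("cluster allele frequencies required to spike individuals")
    nclus = p_cluster.shape[0]
    if nclus < 2:
        raise ValueError("need at least two clusters to spike admixed/hybrid individuals")
    if tree_spec is None:
        tree_spec = (nclus,)
    pairs = _sibling_pairs(tree_spec)

    rng = np.random.default_rng(seed)
    n, L = gm.n_individuals, gm.n_loci
    u = rng.random(n)
    adm_rows = np.where(u < admixed_fraction)[0]
    hyb_rows = np.where((u >= admixed_fraction) & (u < admixed_fraction + hybrid_fraction))[0]

    alleles = gm.alleles.copy()
    kind = truth.kind.copy()
    q_true = dict(truth.q_true)
    hybrid_parents = dict(truth.hybrid_parents)

    for i in adm_rows:
        c1, c2 = pairs[rng.integers(len(pairs))]
        w = rng.dirichlet(np.ones(2))
        q = np.zeros(nclus)
        q[c1], q[c2] = w
        for l in range(L):
            for slot in (0, 1):
                src = c1 if rng.random() < w[0] else c2
                alleles[i, l, slot] = rng.choice(p_cluster.shape[2], p=p_cluster[src, l]) + 1
        kind[i] = "admixed"
        q_true[int(i)] = q

    origin_law = np.array([0.25, 0.5, 0.25])
    for i in hyb_rows:
        c1, c2 = pairs[rng.integers(len(pairs))]
        for l in range(L):
            w = rng.choice(3, p=origin_law)  # 0: both c1, 1: one each, 2: both c2
            src = {0: (c1, c1), 1: (c1, c2), 2: (c2, c2)}[w]
            for slot, sc in enumerate(src):
                alleles[i, l, slot] = rng.choice(p_cluster.shape[2], p=p_cluster[sc, l]) + 1
        kind[i] = "f2"
        hybrid_parents[int(i)] = (int(c1), int(c2))

    new_truth = SimTruth(
        lineage=truth.lineage,
        cluster=truth.cluster,
        kind=kind,
        q_true=q_true,
        hybrid_parents=hybrid_parents,
        pi=truth.pi,
        p_lineage=truth.p_lineage,
        p_cluster=truth.p_cluster,
        realized_missing_rate=truth.realized_missing_rate,
    )
    gm2 = GenotypeMatrix(list(gm.individual_ids), list(gm.locus_names), alleles, gm.missing_mask.copy())
    return gm2, new_truth


def two_deme_config(F: float, n_per_deme: int, seed: int = 0, L: int = 13, A: int = 14) -> SimConfig:
    """Convenience config: two clean demes drifted ``F`` from a shared ancestor."""
    return SimConfig(
        seed=seed,
        L=L,
        alleles_per_locus=A,
        tree_spec=(2,),
        F_level1=0.01,  # near-identity ancestral layer; clusters carry the drift
        F_level2=F,
        n_sites=2,
        n_per_site=n_per_deme,
        site_mixtures=np.array([[1.0, 0.0], [0.0, 1.0]]),
        missing_rate=0.0,
        admixed_fraction=0.0,
        hybrid_fraction=0.0,
    )
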