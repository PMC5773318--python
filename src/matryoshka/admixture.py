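"""Bayesian clustering under the admixture model, by Gibbs sampling.

The model: each individual i has admixture proportions ``q_i`` over K
clusters (Dirichlet(alpha) prior with a single symmetric alpha updated by
Metropolis on Uniform(0, alpha_max)); each allele copy independently picks
an origin cluster from ``q_i`` and then an allele from that cluster's
frequencies.  Under the *correlated* frequency model (the default), each
cluster's frequencies at a locus drift from shared ancestral frequencies
``pi_l`` with a cluster-specific intensity ``F_k`` — the multiallelic
Balding-Nichols / Dirichlet prior ``P_kl ~ Dir(pi_l (1-F_k)/F_k)``.  Under
the *independent* model the prior is a flat ``Dir(1)``.  Missing allele
copies contribute nothing to the likelihood (no imputation).

Replicate chains are reconciled by Hungarian alignment on the Q-overlap
matrix (the exact solution of the label-switching problem for averaging a
handful of runs, replacing heuristic CLUMPP searches).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import _kernels
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ChainConfig:
    """MCMC settings.  Desk-scale defaults; the original study's settings
    (burn 2e5, 2e6 sweeps, 5 chains) are available via these fields."""

    K: int = 2
    burn_in: int = 5_000
    n_sweeps: int = 20_000
    n_chains: int = 5
    frequency_model: str = "correlated"
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in < 0 or self.n_sweeps <= 0:
            raise ValueError("sweep counts must be positive")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.frequency_model not in ("correlated", "independent"):
            raise ValueError("frequency_model must be 'correlated' or 'independent'")


@dataclass
class ChainResult:
    """Posterior means from one chain."""

    Q: np.ndarray  # N x K admixture proportions
    P: np.ndarray  # K x L x Amax allele frequencies (padded with zeros)
    pi_hat: np.ndarray  # L x Amax ancestral frequencies
    F_hat: np.ndarray  # K drift parameters
    alpha_hat: float
    loglik_trace: np.ndarray
    n_alleles: np.ndarray  # alleles per locus
    empty_cluster_fraction: float = 0.0

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Argmax-Q labels; ties broken by lowest cluster index."""
        return self.Q.argmax(axis=1)


@dataclass
class AlignedRuns:
    """Replicate chains with labels permuted onto the first run."""

    runs: list[ChainResult]
    permutations: list[np.ndarray]
    mean_Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_Q = np.mean([r.Q for r in self.runs], axis=0)

    @property
    def K(self) -> int:
        return self.runs[0].K

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def encode_allele_indices(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Map allele codes to dense per-locus indices 0..A_l-1 (missing = -1).

    Returns (codes N x L x 2 int32, n_alleles per locus, per-locus sorted
    allele code table for decoding).
    """
    N, L = gm.n_individuals, gm.n_loci
    codes = np.full((N, L, 2), -1, dtype=np.int32)
    tables: list[np.ndarray] = []
    n_alleles = np.empty(L, dtype=np.int64)
    for l in range(L):
        typed = ~gm.missing_mask[:, l]
        vals = np.unique(gm.alleles[typed, l, :])
        if vals.size == 0:
            vals = np.array([1], dtype=np.int32)  # fully untyped locus
        lut = {int(v): i for i, v in enumerate(vals)}
        tables.append(vals)
        n_alleles[l] = len(vals)
        rows = np.where(typed)[0]
        for c in (0, 1):
            codes[rows, l, c] = [lut[int(v)] for v in gm.alleles[rows, l, c]]
    return codes, n_alleles, tables


def run_admixture_chain(gm: GenotypeMatrix, cfg: ChainConfig, seed: int | None = None) -> ChainResult:
    """Run one Gibbs chain and return posterior means."""
    if gm.missing_mask.all(axis=1).any():
        raise ValueError("every individual needs at least one typed locus")
    codes, n_alleles, _ = encode_allele_indices(gm)
    chain_seed = int(cfg.seed if seed is None else seed) % (2**31 - 1)
    Q, P, pi, F, alpha, trace, empty_frac = _kernels.admixture_gibbs(
        codes,
        n_alleles,
        cfg.K,
        cfg.frequency_model == "correlated",
        cfg.alpha_init,
        cfg.alpha_max,
        cfg.burn_in,
        cfg.n_sweeps,
        chain_seed,
    )
    if not np.isfinite(trace).all():
        raise FloatingPointError("non-finite log-likelihood in admixture chain")
    if empty_frac > 0.5:
        logger.warning(
            "cluster empty for %.0f%% of sweeps at K=%d: K is likely too large",
            100 * empty_frac,
            cfg.K,
        )
    return ChainResult(Q, P, pi, F, float(alpha), trace, n_alleles, empty_frac)


def run_replicates(gm: GenotypeMatrix, cfg: ChainConfig) -> AlignedRuns:
    """Run ``cfg.n_chains`` replicate chains and align their labels."""
    runs = [
        run_admixture_chain(gm, cfg, seed=cfg.seed + 97 * (j + 1))
        for j in range(cfg.n_chains)
    ]
    return align_runs(runs)


def align_runs(runs: list[ChainResult]) -> AlignedRuns:
    """Permute cluster labels of each run onto the first by Hungarian
    assignment maximizing the Q-overlap  sum_i sum_k q_ref[i,k] q_run[i,s(k)]."""
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    N = runs[0].Q.shape[0]
    for r in runs[1:]:
        if r.K != K or r.Q.shape[0] != N:
            raise ValueError("all runs must share N and K")
    ref = runs[0].Q
    aligned: list[ChainResult] = []
    perms: list[np.ndarray] = []
    for r in runs:
        overlap = ref.T @ r.Q  # K x K
        row, col = linear_sum_assignment(-overlap)
        perm = np.empty(K, dtype=np.int64)
        perm[row] = col  # reference label k takes the run's column perm[k]
        aligned.append(
            replace(
                r,
                Q=r.Q[:, perm].copy(),
                P=r.P[perm].copy(),
                F_hat=r.F_hat[perm].copy(),
            )
        )
        perms.append(perm)
    return AlignedRuns(aligned, perms)
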