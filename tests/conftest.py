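import numpy as np
import pytest

from matryoshka import GenotypeMatrix, SimConfig, simulate_hierarchy
from matryoshka.admixture import ChainResult, AlignedRuns
from matryoshka.simulate import two_deme_config


def make_gm(alleles, ids=None, loci=None):
    """GenotypeMatrix from an (N, L, 2) array (0 = missing)."""
    alleles = np.asarray(alleles, dtype=np.int32)
    n, l, _ = alleles.shape
    ids = ids or [f"i{k}" for k in range(n)]
    loci = loci or [f"L{k}" for k in range(l)]
    return GenotypeMatrix(ids, loci, alleles)


def aligned_from_qs(q_list):
    """AlignedRuns stub holding given per-run Q matrices."""
    runs = []
    for q in q_list:
        q = np.asarray(q, dtype=float)
        k = q.shape[1]
        runs.append(
            ChainResult(
                Q=q,
                P=np.zeros((k, 1, 1)),
                pi_hat=np.zeros((1, 1)),
                F_hat=np.full(k, 0.1),
                alpha_hat=1.0,
                loglik_trace=np.zeros(1),
                n_alleles=np.ones(1, dtype=np.int64),
            )
        )
    return AlignedRuns(runs, [np.arange(runs[0].K) for _ in runs])


@pytest.fixture(scope="session")
def two_demes():
    """Two clean demes at drift F = 0.2, 100 individuals each."""
    gm, hier, truth = simulate_hierarchy(two_deme_config(0.2, 100, seed=7))
    return gm, truth


@pytest.fixture(scope="session")
def panmictic():
    """A single panmictic cluster of 150 individuals."""
    cfg = SimConfig(seed=5, tree_spec=(1,), F_level1=0.2, F_level2=0.01,
                    n_sites=2, n_per_site=75, missing_rate=0.0,
                    admixed_fraction=0.0, hybrid_fraction=0.0)
    gm, hier, truth = simulate_hierarchy(cfg)
    return gm, truth


@pytest.fixture(scope="session")
def three_clusters():
    """Three well-separated clusters (drift 0.25), 80 individuals each."""
    cfg = SimConfig(seed=13, tree_spec=(3,), F_level1=0.01, F_level2=0.25,
                    n_sites=3, n_per_site=80, missing_rate=0.0,
                    admixed_fraction=0.0, hybrid_fraction=0.0)
    gm, hier, truth = simulate_hierarchy(cfg)
    return gm, truth
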