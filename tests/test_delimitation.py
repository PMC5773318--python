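"""Threshold assignment rule, method discordance, congruence, recursion."""

from itertools import permutations

import numpy as np
import pytest

from matryoshka.admixture import ChainConfig
from matryoshka.delimit import (
    DelimitConfig,
    congruent_k,
    method_discordance,
    russian_doll,
    threshold_assign,
)

from conftest import aligned_from_qs

LIGHT = DelimitConfig(chain=ChainConfig(burn_in=400, n_sweeps=1500, n_chains=3), k_max=3)


# ---------------------------------------------------------------------------
# the >0.75-in-every-run / >0.1-component rule
# ---------------------------------------------------------------------------


def test_pure_when_above_threshold_in_every_run():
    q = np.array([[0.80, 0.15, 0.05]])
    dec = threshold_assign(aligned_from_qs([q] * 5))[0]
    assert dec.status == "pure" and dec.pure_cluster == 0


def test_single_run_below_threshold_makes_admixed():
    qs = [np.array([[0.74, 0.26, 0.0]])] + [np.array([[0.80, 0.20, 0.0]])] * 4
    dec = threshold_assign(aligned_from_qs(qs))[0]
    assert dec.status == "admixed"
    assert dec.admixed_set == (0, 1)  # mean (0.788, 0.212, 0) > 0.1 for both


def test_component_threshold_is_strict_inequality():
    q = np.array([[0.55, 0.35, 0.10]])
    dec = threshold_assign(aligned_from_qs([q] * 5))[0]
    assert dec.status == "admixed"
    assert dec.admixed_set == (0, 1)  # 0.10 is NOT > 0.1


def test_pure_threshold_is_strict_inequality():
    q = np.array([[0.75, 0.25]])
    dec = threshold_assign(aligned_from_qs([q] * 5))[0]
    assert dec.status == "admixed"


def test_unassignable_when_nothing_clears_noise_floor():
    q = np.full((1, 12), 1 / 12)
    dec = threshold_assign(aligned_from_qs([q] * 3))[0]
    assert dec.status == "unassignable"


def test_raising_tau_pure_shrinks_pure_set():
    rng = np.random.default_rng(0)
    q = rng.dirichlet(np.full(3, 0.3), size=200)
    aligned = aligned_from_qs([q] * 5)
    pure_sets = []
    for tau in (0.6, 0.75, 0.9):
        dec = threshold_assign(aligned, tau_pure=tau)
        pure_sets.append({d.index for d in dec if d.status == "pure"})
    assert pure_sets[2] <= pure_sets[1] <= pure_sets[0]


# ---------------------------------------------------------------------------
# method discordance
# ---------------------------------------------------------------------------


def brute_force_discordance(a, b):
    """Exhaustive minimum mismatch over all K! label matchings."""
    ks = np.unique(b)
    best = len(a)
    for perm in permutations(ks):
        mapping = dict(zip(ks, perm))
        best = min(best, sum(x != mapping[y] for x, y in zip(a, b)))
    return best / len(a)


def test_identical_labelings_zero():
    a = np.array([0, 1, 2, 0, 1, 2])
    frac, _ = method_discordance(a, a)
    assert frac == 0


def test_label_permutation_absorbed():
    a = np.array([0, 0, 1, 1, 2, 2])
    b = np.array([2, 2, 0, 0, 1, 1])
    frac, mapping = method_discordance(a, b)
    assert frac == 0
    assert mapping == {2: 0, 0: 1, 1: 2}


@pytest.mark.parametrize("k", [2, 3, 4])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_discordance_equals_bruteforce(k, seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, k, size=100)
    b = a.copy()
    flips = rng.choice(100, size=5, replace=False)
    b[flips] = (b[flips] + 1) % k
    perm = rng.permutation(k)
    b = perm[b]
    frac, _ = method_discordance(a, b)
    assert frac == pytest.approx(brute_force_discordance(a, b))


def test_planted_disagreements_fraction():
    a = np.array([0] * 50 + [1] * 50)
    b = a.copy()
    b[:5] = 1
    frac, _ = method_discordance(a, b)
    assert frac == pytest.approx(0.05)


def test_differing_k_raises():
    with pytest.raises(ValueError):
        method_discordance(np.array([0, 1, 2]), np.array([0, 1, 1]))


# ---------------------------------------------------------------------------
# congruence and recursion (light MCMC)
# ---------------------------------------------------------------------------


def test_congruent_k_panmictic_is_one(panmictic):
    gm, _ = panmictic
    k, labels, diag = congruent_k(gm, np.arange(gm.n_individuals), LIGHT)
    assert k == 1


def test_congruent_k_three_clusters(three_clusters):
    gm, truth = three_clusters
    k, labels, diag = congruent_k(gm, np.arange(gm.n_individuals), LIGHT, seed_salt=5)
    assert k == 3
    from sklearn.metrics import adjusted_rand_score
    keep = labels >= 0
    assert adjusted_rand_score(truth.cluster[keep], labels[keep]) >= 0.95


def test_russian_doll_single_cluster_is_single_leaf(panmictic):
    gm, _ = panmictic
    tree = russian_doll(gm, LIGHT)
    assert tree.root.is_leaf
    assert tree.root.accepted_k == 1


def test_russian_doll_two_demes(two_demes):
    gm, truth = two_demes
    tree = russian_doll(gm, LIGHT)
    assert len(tree.leaves()) == 2
    # leaves plus exclusion lists exactly partition the input
    lab = tree.leaf_labels()
    excluded = tree.excluded()
    assert set(np.where(lab >= 0)[0]) | set(excluded) == set(range(gm.n_individuals))
    assert not set(np.where(lab >= 0)[0]) & set(excluded)


def test_tree_invariant_to_input_order(two_demes):
    gm, _ = two_demes
    tree1 = russian_doll(gm, LIGHT)
    rng = np.random.default_rng(0)
    perm = rng.permutation(gm.n_individuals)
    tree2 = russian_doll(gm.subset(perm), LIGHT)
    sets1 = sorted(tuple(sorted(tree1.individual_ids[i] for i in lf.members))
                   for lf in tree1.leaves())
    sets2 = sorted(tuple(sorted(tree2.individual_ids[i] for i in lf.members))
                   for lf in tree2.leaves())
    assert sets1 == sets2
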