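"""Differentiation statistics against hand-evaluated oracles."""

import numpy as np
import pytest

from matryoshka.stats import (
    allele_identity_sqdist,
    allele_stats,
    amova,
    dest_infinite_sample,
    genotypic_ld,
    jost_dest,
    per_locus_global_fst,
    theta_infinite_sample,
    wc_components,
    wc_fst,
)
from matryoshka import SimConfig, simulate_hierarchy
from matryoshka.simulate import two_deme_config

from conftest import make_gm


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def wc_oracle_six_genotypes():
    """Hand evaluation of the WC84 components on the worked 6-genotype
    table: deme1 = {A/A, A/A, A/B}, deme2 = {B/B, A/B, B/B}, one locus."""
    r = 2
    n1 = n2 = 3
    nbar = 3.0
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)  # = 3
    out = {}
    for allele, p1, p2, h1, h2 in [("A", 5 / 6, 1 / 6, 1 / 3, 1 / 3),
                                   ("B", 1 / 6, 5 / 6, 1 / 3, 1 / 3)]:
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        out[allele] = (a, b, c)
    return out


def six_genotype_table():
    arr = np.array(
        [[[1, 1]], [[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]], [[2, 2]]], dtype=np.int32
    )
    gm = make_gm(arr)
    groups = {"d1": np.arange(3), "d2": np.arange(3, 6)}
    return gm, groups


def test_wc_components_match_hand_evaluation():
    gm, groups = six_genotype_table()
    comp = wc_components(gm, groups)
    oracle = wc_oracle_six_genotypes()
    # allele codes 1, 2 occupy columns 1, 2 of the component arrays
    for col, allele in [(1, "A"), (2, "B")]:
        a, b, c = oracle[allele]
        assert comp.a[0, col] == pytest.approx(a)
        assert comp.b[0, col] == pytest.approx(b)
        assert comp.c[0, col] == pytest.approx(c)
    tot_a = sum(v[0] for v in oracle.values())
    tot = sum(sum(v) for v in oracle.values())
    assert comp.theta == pytest.approx(tot_a / tot)


def test_fixed_differences_give_theta_one():
    arr = np.ones((20, 5, 2), dtype=np.int32)
    arr[10:] = 2
    gm = make_gm(arr)
    theta, _ = wc_fst(gm, {"a": np.arange(10), "b": np.arange(10, 20)}, n_perm=0)
    assert theta.loc["a", "b"] == pytest.approx(1.0)


def test_duplicated_group_gives_zero_theta(two_demes):
    gm, truth = two_demes
    idx = np.where(truth.cluster == 0)[0]
    comp = wc_components(gm, {"a": idx, "b": idx})
    assert abs(comp.theta) < 0.01


def test_theta_invariant_to_relabeling_and_order(two_demes):
    gm, truth = two_demes
    groups = {"a": np.where(truth.cluster == 0)[0], "b": np.where(truth.cluster == 1)[0]}
    base = wc_components(gm, groups).theta
    # relabel alleles (bijective map) and shuffle individuals
    rng = np.random.default_rng(0)
    relab = gm.alleles.copy()
    relab[relab > 0] = relab[relab > 0] * 7 % 101 + 1
    gm2 = make_gm(relab)
    assert wc_components(gm2, groups).theta == pytest.approx(base)
    perm = rng.permutation(gm.n_individuals)
    inv = {p: i for i, p in enumerate(perm)}
    gm3 = gm.subset(perm)
    groups3 = {k: np.array([inv[i] for i in v]) for k, v in groups.items()}
    assert wc_components(gm3, groups3).theta == pytest.approx(base)


def test_theta_estimator_consistency():
    """theta at n = 500/deme sits within 0.02 of its infinite-sample limit."""
    for seed in (0, 1):
        gm, _, truth = simulate_hierarchy(two_deme_config(0.2, 500, seed=seed))
        groups = {"a": np.where(truth.cluster == 0)[0], "b": np.where(truth.cluster == 1)[0]}
        est = wc_components(gm, groups).theta
        limit = theta_infinite_sample({"a": truth.p_cluster[0], "b": truth.p_cluster[1]})
        assert abs(est - limit) < 0.02


def test_permutation_p_small_for_real_structure(two_demes):
    gm, truth = two_demes
    groups = {"a": np.where(truth.cluster == 0)[0], "b": np.where(truth.cluster == 1)[0]}
    theta, p = wc_fst(gm, groups, n_perm=99, seed=1)
    assert p.loc["a", "b"] == pytest.approx(1 / 100)


def test_per_locus_global_fst_flags_outlier_locus():
    # locus 0 fixed difference, others identical frequencies
    rng = np.random.default_rng(2)
    arr = rng.integers(1, 5, size=(100, 5, 2)).astype(np.int32)
    arr[:50, 0, :] = 1
    arr[50:, 0, :] = 2
    gm = make_gm(arr)
    df = per_locus_global_fst(gm, {"a": np.arange(50), "b": np.arange(50, 100)})
    assert df["theta"].idxmax() == gm.locus_names[0]
    assert df.attrs["mean"] == pytest.approx(np.nanmean(df["theta"].values))


def test_per_locus_fst_zero_for_duplicated_group(two_demes):
    gm, truth = two_demes
    idx = np.where(truth.cluster == 0)[0]
    df = per_locus_global_fst(gm, {"a": idx, "b": idx})
    assert np.nanmax(np.abs(df["theta"].values)) < 0.05


# ---------------------------------------------------------------------------
# Jost's D_est
# ---------------------------------------------------------------------------


def test_dest_limits_disjoint_and_identical():
    p1 = np.zeros((3, 8))
    p2 = np.zeros((3, 8))
    p1[:, :4] = 0.25
    p2[:, 4:] = 0.25
    assert dest_infinite_sample({"a": p1, "b": p2}) == pytest.approx(1.0)
    assert dest_infinite_sample({"a": p1, "b": p1}) == pytest.approx(0.0)


def test_dest_near_one_on_disjoint_sample():
    rng = np.random.default_rng(4)
    arr = np.empty((60, 6, 2), dtype=np.int32)
    arr[:30] = rng.integers(1, 5, size=(30, 6, 2))
    arr[30:] = rng.integers(5, 9, size=(30, 6, 2))
    gm = make_gm(arr)
    dest, _ = jost_dest(gm, {"a": np.arange(30), "b": np.arange(30, 60)}, n_perm=0)
    assert dest.loc["a", "b"] > 0.95


def test_dest_positive_and_below_fst_regime(two_demes):
    gm, truth = two_demes
    groups = {"a": np.where(truth.cluster == 0)[0], "b": np.where(truth.cluster == 1)[0]}
    dest, p = jost_dest(gm, groups, n_perm=99, seed=2)
    assert 0 < dest.loc["a", "b"] < 1
    assert p.loc["a", "b"] == pytest.approx(1 / 100)


# ---------------------------------------------------------------------------
# allele counts / private alleles
# ---------------------------------------------------------------------------


def test_allele_stats_toy_oracle():
    arr = np.array(
        [
            [[1, 2], [1, 1]],
            [[2, 2], [1, 3]],
            [[1, 3], [2, 2]],
            [[3, 3], [2, 2]],
        ],
        dtype=np.int32,
    )
    gm = make_gm(arr)
    st = allele_stats(gm, {"g1": np.array([0, 1]), "g2": np.array([2, 3])})
    tab = st["per_locus"].set_index(["group", "locus"])
    # locus L0: g1 sees {1,2}, g2 sees {1,3}; private: g1 {2}, g2 {3}
    assert tab.loc[("g1", "L0"), "na"] == 2
    assert tab.loc[("g2", "L0"), "na"] == 2
    assert tab.loc[("g1", "L0"), "np"] == 1
    assert tab.loc[("g2", "L0"), "np"] == 1
    # locus L1: g1 sees {1,3}, g2 sees {2}; everything private
    assert tab.loc[("g1", "L1"), "np"] == 2
    assert tab.loc[("g2", "L1"), "np"] == 1


def test_single_group_all_alleles_private(two_demes):
    gm, _ = two_demes
    st = allele_stats(gm, {"only": np.arange(gm.n_individuals)})
    assert (st["summary"]["np_total"] == st["summary"]["na_total"]).all()


# ---------------------------------------------------------------------------
# genotypic linkage disequilibrium
# ---------------------------------------------------------------------------


def test_duplicated_locus_significant_after_bonferroni():
    rng = np.random.default_rng(5)
    base = rng.integers(1, 5, size=(80, 1, 2)).astype(np.int32)
    indep = rng.integers(1, 5, size=(80, 1, 2)).astype(np.int32)
    arr = np.concatenate([base, base, indep], axis=1)
    gm = make_gm(arr)
    df = genotypic_ld(gm, n_perm=2000, seed=3)
    row = df[(df.locus1 == "L0") & (df.locus2 == "L1")].iloc[0]
    assert row.significant
    assert df.attrs["n_pairs"] == 3


def test_ld_pair_with_single_genotype_is_na():
    arr = np.ones((30, 2, 2), dtype=np.int32)  # locus 0 monomorphic
    arr[:, 1, 0] = np.arange(30) % 3 + 1
    arr[:, 1, 1] = arr[:, 1, 0]
    gm = make_gm(arr)
    df = genotypic_ld(gm, n_perm=100, seed=1)
    assert np.isnan(df.iloc[0]["G"])


def test_bonferroni_count_monotone_in_alpha():
    rng = np.random.default_rng(6)
    base = rng.integers(1, 4, size=(60, 1, 2)).astype(np.int32)
    arr = np.concatenate([base, base, rng.integers(1, 4, size=(60, 2, 2))], axis=1)
    gm = make_gm(arr)
    counts = [
        genotypic_ld(gm, n_perm=500, alpha=a, seed=7).attrs["n_significant"]
        for a in (0.2, 0.05, 0.01)
    ]
    assert counts[0] >= counts[1] >= counts[2]


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def amova_oracle(D2, groups, pops):
    """Direct sums-of-squares decomposition on the distance matrix."""
    n = D2.shape[0]
    idx = np.arange(n)

    def ssd(members):
        m = len(members)
        s = sum(D2[i, j] for i in members for j in members if i < j)
        return s / m

    ssd_t = ssd(idx)
    ssd_wg = sum(ssd(idx[groups == g]) for g in np.unique(groups))
    ssd_wp = sum(ssd(idx[pops == p]) for p in np.unique(pops))
    G = np.unique(groups).size
    P = np.unique(pops).size
    df = (G - 1, P - G, n - P)
    ss = (ssd_t - ssd_wg, ssd_wg - ssd_wp, ssd_wp)
    ms = tuple(s / d for s, d in zip(ss, df))
    # solve the expected-mean-square system numerically
    n_p = np.array([np.sum(pops == p) for p in np.unique(pops)], float)
    pop_group = np.array([groups[pops == p][0] for p in np.unique(pops)])
    n_g = np.array([np.sum(groups == g) for g in np.unique(groups)], float)
    term_g = sum(n_p[pop_group == g] @ n_p[pop_group == g] / n_g[gi]
                 for gi, g in enumerate(np.unique(groups)))
    n1 = (n - term_g) / df[1]
    n2 = (term_g - (n_p**2).sum() / n) / df[0]
    n3 = (n - (n_g**2).sum() / n) / df[0]
    A = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    sig = np.linalg.solve(A, np.array(ms))
    return ss, df, sig


def test_amova_matches_direct_ss_arithmetic():
    rng = np.random.default_rng(8)
    arr = rng.integers(1, 4, size=(8, 4, 2)).astype(np.int32)
    gm = make_gm(arr)
    groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    pops = np.array([0, 0, 1, 1, 2, 2, 3, 3])
    res = amova(gm, groups, pops, n_perm=0)
    D2 = allele_identity_sqdist(gm)
    ss, df, sig = amova_oracle(D2, groups, pops)
    assert res.ss == pytest.approx(ss)
    assert res.df == df
    assert (res.sigma_a, res.sigma_b, res.sigma_c) == pytest.approx(tuple(sig))
    assert sum(res.percentages) == pytest.approx(100.0, abs=0.01)


def test_amova_null_has_small_phi_ct(panmictic):
    gm, _ = panmictic
    n = gm.n_individuals
    rng = np.random.default_rng(9)
    groups = rng.integers(0, 2, size=n)
    pops = groups * 2 + rng.integers(0, 2, size=n)
    res = amova(gm, groups, pops, n_perm=99, seed=3)
    assert abs(res.phi_ct) < 0.05
    assert res.p_ct > 0.01


def test_amova_structured_data_phi_ordering():
    gm, _, truth = simulate_hierarchy(SimConfig(seed=14, n_sites=4, n_per_site=60))
    res = amova(gm, truth.lineage, truth.cluster, n_perm=0)
    assert res.phi_st >= res.phi_ct > 0
    assert sum(res.percentages) == pytest.approx(100.0, abs=0.01)
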