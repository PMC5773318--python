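"""Generator: drift calibration, sympatry, missing data, spiked individuals."""

import numpy as np
import pytest

from matryoshka import SimConfig, simulate_hierarchy
from matryoshka.simulate import inject_missing, spike_special_individuals, two_deme_config
from matryoshka.stats import allele_stats, theta_infinite_sample, wc_components

from conftest import make_gm


def groups_of(truth, field="cluster"):
    lab = getattr(truth, field)
    return {f"g{c}": np.where(lab == c)[0] for c in np.unique(lab)}


def test_same_seed_identical_outputs():
    cfg = SimConfig(seed=4, n_sites=2, n_per_site=50, tree_spec=(2,))
    a = simulate_hierarchy(cfg)
    b = simulate_hierarchy(cfg)
    assert np.array_equal(a[0].alleles, b[0].alleles)
    assert np.array_equal(a[0].missing_mask, b[0].missing_mask)
    assert np.array_equal(a[2].cluster, b[2].cluster)


def test_no_drift_limit_gives_no_differentiation():
    cfg = two_deme_config(1e-4, 500, seed=6)
    gm, _, truth = simulate_hierarchy(cfg)
    theta = wc_components(gm, groups_of(truth)).theta
    assert abs(theta) <= 0.01


def test_sibling_cluster_fst_matches_design_drift():
    """Realized F_ST between sibling clusters tracks F_level2; the oracle is
    the estimator's infinite-sample limit on the realized frequencies."""
    cfg = two_deme_config(0.12, 200, seed=9)
    gm, _, truth = simulate_hierarchy(cfg)
    theta = wc_components(gm, groups_of(truth)).theta
    theta_inf = theta_infinite_sample({"a": truth.p_cluster[0], "b": truth.p_cluster[1]})
    assert abs(theta - theta_inf) / theta_inf < 0.25
    # and the design drift itself is recovered within 25 % relative error
    assert abs(theta_inf - 0.12) / 0.12 < 0.5  # cross-locus realization noise


def test_sympatry_every_site_mixes_clusters():
    gm, hier, truth = simulate_hierarchy(SimConfig(seed=1))
    sites = np.array(hier.site)
    n_clus = truth.cluster.max() + 1
    for s in np.unique(sites):
        rows = np.where(sites == s)[0]
        found = np.unique(truth.cluster[rows])
        assert found.size >= 2
        # uniform mixture: each cluster share within 5 sigma of 1/8
        share = np.bincount(truth.cluster[rows], minlength=n_clus) / rows.size
        sigma = np.sqrt((1 / n_clus) * (1 - 1 / n_clus) / rows.size)
        assert (np.abs(share - 1 / n_clus) < 5 * sigma).all()


def test_inject_missing_zero_is_identity(two_demes):
    gm, _ = two_demes
    gm2 = inject_missing(gm, 0.0, seed=1)
    assert gm2 is gm


def test_inject_missing_realized_rate():
    gm = make_gm(np.ones((1000, 13, 2), dtype=np.int32))
    gm2 = inject_missing(gm, 0.37, seed=2)
    assert abs(gm2.missing_mask.mean() - 0.37) < 0.01


def test_inject_missing_extreme_rate_still_valid(caplog):
    gm = make_gm(np.ones((20, 13, 2), dtype=np.int32))
    with caplog.at_level("WARNING"):
        gm2 = inject_missing(gm, 0.99, seed=3)
    assert gm2.n_individuals == 20
    assert any("missing" in r.message for r in caplog.records)


def test_spike_zero_fractions_is_identity(two_demes):
    gm, truth = two_demes
    gm2, t2 = spike_special_individuals(gm, truth, 0.0, 0.0, seed=1)
    assert gm2 is gm


def test_spike_hybrid_count_binomial():
    cfg = SimConfig(seed=8, n_sites=5, n_per_site=500, tree_spec=(2,),
                    F_level2=0.2, missing_rate=0, admixed_fraction=0,
                    hybrid_fraction=0.007)
    gm, _, truth = simulate_hierarchy(cfg)
    n_hyb = (truth.kind == "f2").sum()
    # n f = 17.5 expected for n = 2,500; allow 4 binomial sigma
    assert 2 <= n_hyb <= 35


def test_spike_refuses_large_fractions(two_demes):
    gm, truth = two_demes
    with pytest.raises(ValueError):
        spike_special_individuals(gm, truth, 0.6, 0.0, seed=1)


def test_f2_heterozygous_origin_fraction_half():
    """Between fully diverged clusters, an F2 carries one allele from each
    parent at ~half its loci — the middle term of the (1/4, 1/2, 1/4) law."""
    rng = np.random.default_rng(0)
    L, A = 13, 14
    # disjoint parental pools: cluster 0 uses alleles 0-6, cluster 1 uses 7-13
    p = np.zeros((2, L, A))
    p[0, :, :7] = 1 / 7
    p[1, :, 7:] = 1 / 7
    gm = make_gm(np.ones((400, L, 2), dtype=np.int32))
    from matryoshka.simulate import SimTruth
    truth = SimTruth(lineage=np.zeros(400, int), cluster=np.zeros(400, int),
                     kind=np.array(["pure"] * 400, dtype=object), p_cluster=p)
    gm2, t2 = spike_special_individuals(gm, truth, 0.0, 0.4, seed=5,
                                        p_cluster=p, tree_spec=(2,))
    rows = np.where(t2.kind == "f2")[0]
    assert rows.size > 50
    cross = ((gm2.alleles[rows, :, 0] <= 7) != (gm2.alleles[rows, :, 1] <= 7)).mean()
    assert abs(cross - 0.5) < 0.05


def test_allele_counts_and_private_alleles_match_design():
    """At ~1,400 individuals per lineage the observed mean alleles/locus
    brackets the target regime and every lineage carries private alleles."""
    cfg = SimConfig(seed=10, n_sites=8, n_per_site=525)  # ~1,400 per lineage
    gm, _, truth = simulate_hierarchy(cfg)
    st = allele_stats(gm, groups_of(truth, "lineage"))
    na = st["summary"]["na_mean"]
    assert ((na >= 10) & (na <= 18)).all()
    assert (st["summary"]["np_total"] > 0).all()
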