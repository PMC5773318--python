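"""Differentiation and diversity statistics.

Implements the classical estimators used to quantify how distinct the
delimited groups are:

* Weir & Cockerham's moment estimator of F_ST (theta), from per-locus,
  per-allele variance components a (among populations), b (among
  individuals within populations) and c (within individuals); pairwise
  matrices with permutation p-values, and global per-locus values.
* Jost's D_est with Nei-Chesser bias corrections (harmonic-mean sample
  size, arithmetic multilocus averaging).
* Allele counts (Na) and private alleles (Np) per group.
* Genotypic linkage-disequilibrium G-tests with within-group permutation
  nulls and Bonferroni correction.
* Hierarchical AMOVA (group > population > individual) on the
  allele-identity distance, with Phi-statistics and permutation tests.

Missing data is handled by per-locus pairwise deletion: a locus enters a
comparison only where at least two individuals per group are typed.
Negative theta values are reported, not truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import _kernels
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

Groups = dict[str, np.ndarray]  # group name -> individual indices


def _as_groups(groups) -> Groups:
    out = {}
    for name, idx in groups.items():
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size == 0:
            raise ValueError(f"empty group {name!r}")
        out[str(name)] = idx
    return out


# ---------------------------------------------------------------------------
# allele bookkeeping
# ---------------------------------------------------------------------------


def _group_counts(gm: GenotypeMatrix, groups: Groups):
    """Per group: typed sample size n[g, l], allele counts cnt[g, l, code]
    and single-copy (heterozygous-carrier) counts het[g, l, code]."""
    names = list(groups)
    L = gm.n_loci
    codes = gm.alleles  # raw positive codes; 0 = missing
    amax = int(codes.max()) + 1
    G = len(names)
    n = np.zeros((G, L))
    cnt = np.zeros((G, L, amax))
    het = np.zeros((G, L, amax))
    for g, name in enumerate(names):
        idx = groups[name]
        sub = codes[idx]  # m x L x 2
        typed = ~gm.missing_mask[idx]
        n[g] = typed.sum(axis=0)
        for l in range(L):
            rows = sub[typed[:, l], l, :]
            if rows.size == 0:
                continue
            cnt[g, l] = np.bincount(rows.ravel(), minlength=amax)
            hz = rows[rows[:, 0] != rows[:, 1]]
            if hz.size:
                het[g, l] = np.bincount(hz.ravel(), minlength=amax)
    return names, n, cnt, het


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


@dataclass
class FstComponents:
    """Per-locus, per-allele WC84 variance components and intermediates."""

    locus_names: list[str]
    a: np.ndarray  # L x A
    b: np.ndarray
    c: np.ndarray
    nbar: np.ndarray  # L
    nc: np.ndarray  # L
    pbar: np.ndarray  # L x A
    s2: np.ndarray  # L x A
    hbar: np.ndarray  # L x A
    used: np.ndarray  # L bool: locus entered the ratio

    @property
    def theta(self) -> float:
        num = self.a[self.used].sum()
        den = (self.a + self.b + self.c)[self.used].sum()
        return float(num / den) if den != 0 else np.nan

    def theta_per_locus(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            den = (self.a + self.b + self.c).sum(axis=1)
            out = self.a.sum(axis=1) / den
        out[~self.used] = np.nan
        return out


def wc_components(gm: GenotypeMatrix, groups) -> FstComponents:
    """WC84 a/b/c components for an arbitrary partition into r >= 2 groups."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    _, n, cnt, het = _group_counts(gm, groups)
    r = len(groups)
    L, A = cnt.shape[1], cnt.shape[2]

    a = np.zeros((L, A))
    b = np.zeros((L, A))
    c = np.zeros((L, A))
    nbar_arr = np.zeros(L)
    nc_arr = np.zeros(L)
    pbar_arr = np.zeros((L, A))
    s2_arr = np.zeros((L, A))
    hbar_arr = np.zeros((L, A))
    used = np.zeros(L, dtype=bool)

    for l in range(L):
        ni = n[:, l]
        if (ni < 2).any():
            continue  # pairwise deletion: need >= 2 typed per group
        nbar = ni.mean()
        nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1)
        p_i = cnt[:, l, :] / (2 * ni)[:, None]
        h_i = het[:, l, :] / ni[:, None]
        pbar = (ni[:, None] * p_i).sum(axis=0) / (r * nbar)
        s2 = (ni[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ni[:, None] * h_i).sum(axis=0) / (r * nbar)
        poly = (pbar > 0) & (pbar < 1)
        if not poly.any():
            continue  # monomorphic locus: excluded from ratios
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a[l] = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b[l] = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
        c[l] = hbar / 2
        a[l, ~poly] = b[l, ~poly] = c[l, ~poly] = 0.0
        nbar_arr[l], nc_arr[l] = nbar, nc
        pbar_arr[l], s2_arr[l], hbar_arr[l] = pbar, s2, hbar
        used[l] = True
    return FstComponents(list(gm.locus_names), a, b, c, nbar_arr, nc_arr,
                         pbar_arr, s2_arr, hbar_arr, used)


def _theta_value(gm: GenotypeMatrix, groups: Groups) -> float:
    return wc_components(gm, groups).theta


def _pairwise_permutation(gm, idx1, idx2, stat, n_perm, seed):
    """p-value: share of label permutations with stat_perm >= stat_obs."""
    obs = stat(gm, {"g1": idx1, "g2": idx2})
    if n_perm <= 0 or not np.isfinite(obs):
        return obs, np.nan
    rng = np.random.default_rng(seed)
    pool = np.concatenate([idx1, idx2])
    n1 = idx1.size
    worse = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        val = stat(gm, {"g1": perm[:n1], "g2": perm[n1:]})
        if np.isfinite(val) and val >= obs - 1e-12:
            worse += 1
    return obs, (worse + 1) / (n_perm + 1)


def wc_fst(gm: GenotypeMatrix, groups, n_perm: int = 999, seed: int = 0):
    """Pairwise multilocus theta matrix with permutation p-values.

    Returns ``(theta_df, pval_df)``; monomorphic pairs yield NaN.
    """
    groups = _as_groups(groups)
    names = list(groups)
    theta = pd.DataFrame(np.nan, index=names, columns=names)
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    for i, (na, nb) in enumerate(combinations(names, 2)):
        obs, p = _pairwise_permutation(
            gm, groups[na], groups[nb], _theta_value, n_perm, seed + 7919 * i
        )
        theta.loc[na, nb] = theta.loc[nb, na] = obs
        pvals.loc[na, nb] = pvals.loc[nb, na] = p
    np.fill_diagonal(theta.values, 0.0)
    return theta, pvals


def per_locus_global_fst(gm: GenotypeMatrix, groups) -> pd.DataFrame:
    """Global per-locus theta over all groups, with mean +/- SE over loci."""
    comp = wc_components(gm, groups)
    tl = comp.theta_per_locus()
    df = pd.DataFrame({"locus": gm.locus_names, "theta": tl}).set_index("locus")
    vals = tl[np.isfinite(tl)]
    df.attrs["mean"] = float(vals.mean()) if vals.size else np.nan
    df.attrs["se"] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
    df.attrs["multilocus"] = comp.theta
    return df


# ---------------------------------------------------------------------------
# Jost's D_est
# ---------------------------------------------------------------------------


def _dest_value(gm: GenotypeMatrix, groups: Groups) -> float:
    _, n, cnt, _ = _group_counts(gm, groups)
    r = len(groups)
    L = cnt.shape[1]
    vals = []
    for l in range(L):
        ni = n[:, l]
        if (ni < 2).any():
            continue
        p_i = cnt[:, l, :] / (2 * ni)[:, None]
        ntilde = r / (1.0 / ni).sum()  # harmonic mean sample size
        hs_plug = 1.0 - (p_i**2).sum(axis=1).mean()
        hs = (2 * ntilde / (2 * ntilde - 1)) * hs_plug
        pbar = p_i.mean(axis=0)
        ht = 1.0 - (pbar**2).sum() + hs / (2 * ntilde * r)
        if hs >= 1.0 or ht <= 0:
            logger.warning("locus %s skipped in D_est (H_S >= 1)", gm.locus_names[l])
            continue
        if (pbar > 0).sum() < 2:
            continue  # monomorphic
        d = ((ht - hs) / (1.0 - hs)) * (r / (r - 1.0))
        vals.append(d)
    return float(np.mean(vals)) if vals else np.nan


def jost_dest(gm: GenotypeMatrix, groups, n_perm: int = 999, seed: int = 0):
    """Pairwise Jost's D_est matrix with permutation p-values."""
    groups = _as_groups(groups)
    names = list(groups)
    dest = pd.DataFrame(np.nan, index=names, columns=names)
    pvals = pd.DataFrame(np.nan, index=names, columns=names)
    for i, (na, nb) in enumerate(combinations(names, 2)):
        obs, p = _pairwise_permutation(
            gm, groups[na], groups[nb], _dest_value, n_perm, seed + 104729 * i
        )
        dest.loc[na, nb] = dest.loc[nb, na] = obs
        pvals.loc[na, nb] = pvals.loc[nb, na] = p
    np.fill_diagonal(dest.values, 0.0)
    return dest, pvals


def theta_infinite_sample(freqs: dict[str, np.ndarray]) -> float:
    """WC84 theta evaluated on true per-group allele-frequency arrays
    (each L x A) — the estimator's infinite-sample limit:
    theta -> sum s2 / sum (pbar qbar + s2 / r) with equal weights."""
    mats = np.stack(list(freqs.values()))  # G x L x A
    r, L, _ = mats.shape
    num = den = 0.0
    for l in range(L):
        p_i = mats[:, l, :]
        pbar = p_i.mean(axis=0)
        s2 = ((p_i - pbar) ** 2).sum(axis=0) / (r - 1)
        num += s2.sum()
        den += (pbar * (1 - pbar) + s2 / r).sum()
    return float(num / den)


def dest_infinite_sample(freqs: dict[str, np.ndarray]) -> float:
    """D_est evaluated on true per-group allele-frequency arrays
    (groups x loci x alleles stacked per group) — the estimator's
    infinite-sample limit, used for sanity checks."""
    mats = np.stack(list(freqs.values()))  # G x L x A
    G, L, _ = mats.shape
    vals = []
    for l in range(L):
        p_i = mats[:, l, :]
        hs = 1.0 - (p_i**2).sum(axis=1).mean()
        pbar = p_i.mean(axis=0)
        ht = 1.0 - (pbar**2).sum()
        if hs >= 1.0:
            continue
        vals.append(((ht - hs) / (1.0 - hs)) * (G / (G - 1.0)))
    return float(np.mean(vals)) if vals else np.nan


# ---------------------------------------------------------------------------
# allele counts / private alleles
# ---------------------------------------------------------------------------


def allele_stats(gm: GenotypeMatrix, groups):
    """Na and Np per group.

    Returns a dict with per-group/locus allele counts (``na``), private
    allele counts (``np``), mean +/- SE over loci, and the per-group
    allele-frequency spectra.
    """
    groups = _as_groups(groups)
    names, n, cnt, _ = _group_counts(gm, groups)
    present = cnt > 0  # G x L x A
    na = present.sum(axis=2).astype(float)  # G x L
    groups_with = present.sum(axis=0)  # L x A
    private = present & (groups_with[None, :, :] == 1)
    npriv = private.sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        spectra = cnt / np.where(cnt.sum(axis=2, keepdims=True) == 0, np.nan,
                                 cnt.sum(axis=2, keepdims=True))
    L = gm.n_loci
    table = pd.DataFrame(
        {
            "group": np.repeat(names, L),
            "locus": np.tile(gm.locus_names, len(names)),
            "na": na.ravel(),
            "np": npriv.ravel(),
        }
    )
    summary = pd.DataFrame(
        {
            "group": names,
            "na_mean": na.mean(axis=1),
            "na_se": na.std(axis=1, ddof=1) / np.sqrt(L) if L > 1 else np.nan,
            "np_mean": npriv.mean(axis=1),
            "np_se": npriv.std(axis=1, ddof=1) / np.sqrt(L) if L > 1 else np.nan,
            "np_total": npriv.sum(axis=1),
            "na_total": na.sum(axis=1),
        }
    ).set_index("group")
    summary["private_share"] = summary["np_total"] / summary["na_total"]
    return {"per_locus": table, "summary": summary, "spectra": spectra, "names": names}


# ---------------------------------------------------------------------------
# genotypic linkage disequilibrium
# ---------------------------------------------------------------------------


def _genotype_codes(gm: GenotypeMatrix) -> np.ndarray:
    """Dense integer code of each unordered single-locus genotype
    (-1 where untyped)."""
    N, L = gm.n_individuals, gm.n_loci
    out = np.full((N, L), -1, dtype=np.int64)
    srt = np.sort(gm.alleles, axis=2)
    for l in range(L):
        typed = ~gm.missing_mask[:, l]
        pairs = srt[typed, l, :]
        _, codes = np.unique(pairs, axis=0, return_inverse=True)
        out[typed, l] = codes
    return out


def genotypic_ld(gm: GenotypeMatrix, groups=None, n_perm: int = 10_000,
                 alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """G-tests of genotypic association for every locus pair.

    The null distribution permutes one locus's genotypes among individuals
    (within groups, when ``groups`` is given).  The Bonferroni threshold is
    ``alpha / (L(L-1)/2)``.  Returns a DataFrame (locus1, locus2, G, p,
    significant); ``df.attrs['n_significant']`` holds the Bonferroni count.
    """
    if gm.n_loci < 2:
        raise ValueError("need at least two loci")
    geno = _genotype_codes(gm)
    if groups is None:
        grp = np.zeros(gm.n_individuals, dtype=np.int64)
    else:
        groups = _as_groups(groups)
        grp = np.full(gm.n_individuals, -1, dtype=np.int64)
        for g, name in enumerate(groups):
            grp[groups[name]] = g
        keep = grp >= 0
        geno = np.where(keep[:, None], geno, -1)
        grp = np.where(keep, grp, 0)
    pairs = list(combinations(range(gm.n_loci), 2))
    thresh = alpha / len(pairs)
    recs = []
    for t, (l1, l2) in enumerate(pairs):
        g_obs, p = _kernels.ld_gtest_perm(
            geno[:, l1].copy(), geno[:, l2].copy(), n_perm,
            (seed + 613 * t) % (2**31 - 1), grp
        )
        sig = bool(np.isfinite(p) and p < thresh)
        recs.append((gm.locus_names[l1], gm.locus_names[l2], g_obs, p, sig))
    df = pd.DataFrame(recs, columns=["locus1", "locus2", "G", "p", "significant"])
    df.attrs["n_significant"] = int(df["significant"].sum())
    df.attrs["n_pairs"] = len(pairs)
    df.attrs["bonferroni_threshold"] = thresh
    return df


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Nested AMOVA variance components and Phi-statistics."""

    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    ss: tuple[float, float, float]
    df: tuple[int, int, int]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float = np.nan
    p_sc: float = np.nan
    p_st: float = np.nan

    @property
    def percentages(self) -> tuple[float, float, float]:
        tot = self.sigma_a + self.sigma_b + self.sigma_c
        return (100 * self.sigma_a / tot, 100 * self.sigma_b / tot, 100 * self.sigma_c / tot)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "source": ["among_groups", "among_pops_within_groups", "within_pops"],
                "df": list(self.df),
                "SS": list(self.ss),
                "variance": [self.sigma_a, self.sigma_b, self.sigma_c],
                "pct_total": list(pct),
                "phi": [self.phi_ct, self.phi_sc, self.phi_st],
                "p": [self.p_ct, self.p_sc, self.p_st],
            }
        )


def allele_identity_sqdist(gm: GenotypeMatrix) -> np.ndarray:
    """Inter-individual squared distance sum_l (2 - shared alleles at l),
    rescaled by L/L' over co-typed loci (NaN when no co-typed locus)."""
    N, L = gm.n_individuals, gm.n_loci
    a1 = gm.alleles[:, :, 0].astype(np.int64)
    a2 = gm.alleles[:, :, 1].astype(np.int64)
    typed = ~gm.missing_mask
    D = np.zeros((N, N))
    for i in range(N):
        s = np.maximum(
            (a1[i] == a1).astype(np.int64) + (a2[i] == a2),
            (a1[i] == a2).astype(np.int64) + (a2[i] == a1),
        )  # N x L shared-allele counts vs individual i
        ok = typed[i] & typed
        lprime = ok.sum(axis=1)
        diff = np.where(ok, 2 - s, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = diff * (L / lprime)
        D[i, lprime == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D


def _amova_components(D2, pop_of, group_of, pops_per_group):
    n_pops = int(pop_of.max()) + 1
    n_groups = int(group_of.max()) + 1
    N = D2.shape[0]
    ssd_total, ssd_wg, ssd_wp = _kernels.amova_ss(D2, pop_of, group_of, n_pops, n_groups)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap = ssd_wg - ssd_wp
    df_a, df_b, df_c = n_groups - 1, n_pops - n_groups, N - n_pops
    if df_a < 1 or df_b < 1 or df_c < 1:
        raise ValueError("AMOVA needs >= 2 groups, nested populations and residual df")
    ms_a, ms_b, ms_c = ssd_ag / df_a, ssd_ap / df_b, ssd_wp / df_c

    n_p = np.bincount(pop_of, minlength=n_pops).astype(float)
    n_g = np.bincount(group_of, minlength=n_groups).astype(float)
    sum_np2_by_group = np.zeros(n_groups)
    for p in range(n_pops):
        sum_np2_by_group[pops_per_group[p]] += n_p[p] ** 2
    term_g = (sum_np2_by_group / n_g).sum()
    n1 = (N - term_g) / df_b
    n2 = (term_g - (n_p**2).sum() / N) / df_a
    n3 = (N - (n_g**2).sum() / N) / df_a

    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / n1
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / tot
    phi_sc = sigma_b / (sigma_b + sigma_c)
    phi_st = (sigma_a + sigma_b) / tot
    return (sigma_a, sigma_b, sigma_c, (ssd_ag, ssd_ap, ssd_wp),
            (df_a, df_b, df_c), phi_ct, phi_sc, phi_st)


def amova(gm: GenotypeMatrix, group_labels, pop_labels, n_perm: int = 999,
          seed: int = 0) -> AmovaResult:
    """Hierarchical AMOVA: groups > populations within groups > individuals.

    ``group_labels`` / ``pop_labels`` are per-individual labels (any
    hashable).  Permutation tests: populations among groups for Phi_CT,
    individuals among populations within groups for Phi_SC, individuals
    among all populations for Phi_ST.
    """
    group_labels = np.asarray(group_labels)
    pop_labels = np.asarray(pop_labels)
    if group_labels.shape[0] != gm.n_individuals or pop_labels.shape[0] != gm.n_individuals:
        raise ValueError("labels must cover every individual")
    # dense codes; populations are nested in groups by construction of pairs
    pairs = list(dict.fromkeys(zip(group_labels, pop_labels)))
    pop_code = {pair: i for i, pair in enumerate(pairs)}
    group_names = pd.unique(group_labels)
    grp_code = {g: i for i, g in enumerate(group_names)}
    pop_of = np.array([pop_code[(g, p)] for g, p in zip(group_labels, pop_labels)])
    group_of = np.array([grp_code[g] for g in group_labels])
    pops_per_group = np.empty(len(pairs), dtype=np.int64)
    for pair, i in pop_code.items():
        pops_per_group[i] = grp_code[pair[0]]

    D2 = allele_identity_sqdist(gm)
    if np.isnan(D2).any():
        raise ValueError("individuals with no co-typed loci cannot enter the AMOVA")

    (sa, sb, sc, ss, df, phi_ct, phi_sc, phi_st) = _amova_components(
        D2, pop_of, group_of, pops_per_group
    )
    res = AmovaResult(sa, sb, sc, ss, df, phi_ct, phi_sc, phi_st)

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n_pops = int(pop_of.max()) + 1
        hits_ct = hits_sc = hits_st = 0
        for _ in range(n_perm):
            # Phi_CT: permute whole populations among groups
            perm_groups = rng.permutation(pops_per_group)
            g_of = perm_groups[pop_of]
            try:
                stat = _amova_components(D2, pop_of, g_of, perm_groups)[5]
                if stat >= phi_ct - 1e-12:
                    hits_ct += 1
            except ValueError:
                pass
            # Phi_SC: permute individuals among pops within groups
            p_of = pop_of.copy()
            for g in range(int(group_of.max()) + 1):
                rows = np.where(group_of == g)[0]
                p_of[rows] = p_of[rng.permutation(rows)]
            stat = _amova_components(D2, p_of, group_of, pops_per_group)[6]
            if stat >= phi_sc - 1e-12:
                hits_sc += 1
            # Phi_ST: permute individuals among all populations
            order = rng.permutation(gm.n_individuals)
            stat = _amova_components(D2, pop_of[order], group_of[order], pops_per_group)[7]
            if stat >= phi_st - 1e-12:
                hits_st += 1
        res.p_ct = (hits_ct + 1) / (n_perm + 1)
        res.p_sc = (hits_sc + 1) / (n_perm + 1)
        res.p_st = (hits_st + 1) / (n_perm + 1)
    return res
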