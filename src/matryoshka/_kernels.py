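"""Numba kernels for the Gibbs samplers.

Hot loops only; all model logic is documented in the calling modules.
The numba global RNG is seeded per chain, so chains are deterministic
given their seed and independent of call order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _dirichlet_inplace(conc, n, out):
    s = 0.0
    for a in range(n):
        g = np.random.gamma(conc[a], 1.0)
        if g < 1e-300:
            g = 1e-300
        out[a] = g
        s += g
    for a in range(n):
        out[a] /= s


@njit(cache=True)
def _log_dirichlet(x, conc, n):
    s = 0.0
    tot = 0.0
    for a in range(n):
        tot += conc[a]
        s -= math.lgamma(conc[a])
        s += (conc[a] - 1.0) * math.log(max(x[a], 1e-300))
    return s + math.lgamma(tot)


@njit(cache=True)
def admixture_gibbs(codes, n_alleles, K, correlated, alpha_init, alpha_max,
                    burn, sweeps, seed):
    """Gibbs sampler for the admixture model with (optionally) correlated
    allele frequencies.  Returns posterior means and the log-likelihood
    trace.  ``codes``: N x L x 2 int32 allele indices, -1 = missing."""
    np.random.seed(seed)
    N, L, _ = codes.shape
    Amax = int(n_alleles.max())

    # ancestral frequencies initialised at smoothed observed frequencies
    pi = np.zeros((L, Amax))
    for l in range(L):
        tot = 0.0
        for i in range(N):
            for c in range(2):
                x = codes[i, l, c]
                if x >= 0:
                    pi[l, x] += 1.0
                    tot += 1.0
        for a in range(n_alleles[l]):
            pi[l, a] = (pi[l, a] + 1.0) / (tot + n_alleles[l])

    Q = np.full((N, K), 1.0 / K)
    P = np.zeros((K, L, Amax))
    conc = np.empty(Amax)
    for k in range(K):
        for l in range(L):
            for a in range(n_alleles[l]):
                conc[a] = pi[l, a] * 20.0 + 0.05
            _dirichlet_inplace(conc, n_alleles[l], P[k, l])

    F = np.full(K, 0.1)
    alpha = alpha_init

    cnt_ik = np.zeros((N, K))
    cnt_kla = np.zeros((K, L, Amax))
    probs = np.empty(K)
    qconc = np.empty(K)
    totsweeps = burn + sweeps
    trace = np.empty(totsweeps)
    Qsum = np.zeros((N, K))
    Psum = np.zeros((K, L, Amax))
    pisum = np.zeros((L, Amax))
    Fsum = np.zeros(K)
    alphasum = 0.0
    empty_sweeps = 0
    ktot = np.zeros(K)

    for sw in range(totsweeps):
        # (i) allele-copy origins
        for i in range(N):
            for k in range(K):
                cnt_ik[i, k] = 0.0
        for k in range(K):
            for l in range(L):
                for a in range(n_alleles[l]):
                    cnt_kla[k, l, a] = 0.0
        ll = 0.0
        for i in range(N):
            for l in range(L):
                for c in range(2):
                    x = codes[i, l, c]
                    if x < 0:
                        continue
                    tot = 0.0
                    for k in range(K):
                        w = Q[i, k] * P[k, l, x]
                        probs[k] = w
                        tot += w
                    ll += math.log(max(tot, 1e-300))
                    u = np.random.random() * tot
                    acc = 0.0
                    pick = K - 1
                    for k in range(K):
                        acc += probs[k]
                        if u <= acc:
                            pick = k
                            break
                    cnt_ik[i, pick] += 1.0
                    cnt_kla[pick, l, x] += 1.0
        trace[sw] = ll

        for k in range(K):
            ktot[k] = 0.0
            for l in range(L):
                for a in range(n_alleles[l]):
                    ktot[k] += cnt_kla[k, l, a]
        any_empty = False
        for k in range(K):
            if ktot[k] == 0.0:
                any_empty = True
        if any_empty:
            empty_sweeps += 1

        # (ii) admixture proportions
        for i in range(N):
            for k in range(K):
                qconc[k] = alpha + cnt_ik[i, k]
            _dirichlet_inplace(qconc, K, Q[i])

        # (iii) cluster allele frequencies
        for k in range(K):
            r = (1.0 - F[k]) / F[k]
            for l in range(L):
                for a in range(n_alleles[l]):
                    prior = pi[l, a] * r if correlated else 1.0
                    conc[a] = prior + cnt_kla[k, l, a]
                _dirichlet_inplace(conc, n_alleles[l], P[k, l])

        if correlated:
            # drift parameters: random-walk Metropolis on logit(F_k)
            for k in range(K):
                f = F[k]
                t = math.log(f / (1.0 - f)) + np.random.normal(0.0, 0.3)
                fprop = 1.0 / (1.0 + math.exp(-t))
                if fprop < 1e-5 or fprop > 1.0 - 1e-5:
                    continue
                lr = math.log(fprop * (1.0 - fprop)) - math.log(f * (1.0 - f))
                rold = (1.0 - f) / f
                rnew = (1.0 - fprop) / fprop
                for l in range(L):
                    for a in range(n_alleles[l]):
                        conc[a] = pi[l, a] * rnew
                    lr += _log_dirichlet(P[k, l], conc, n_alleles[l])
                    for a in range(n_alleles[l]):
                        conc[a] = pi[l, a] * rold
                    lr -= _log_dirichlet(P[k, l], conc, n_alleles[l])
                if math.log(np.random.random() + 1e-300) < lr:
                    F[k] = fprop
            # ancestral frequencies: Dirichlet-proposal Metropolis
            piprop = np.empty(Amax)
            pconc = np.empty(Amax)
            for l in range(L):
                nl = n_alleles[l]
                c0 = 200.0
                for a in range(nl):
                    pconc[a] = pi[l, a] * c0 + 0.01
                _dirichlet_inplace(pconc, nl, piprop)
                lr = 0.0
                for k in range(K):
                    r = (1.0 - F[k]) / F[k]
                    for a in range(nl):
                        conc[a] = piprop[a] * r
                    lr += _log_dirichlet(P[k, l], conc, nl)
                    for a in range(nl):
                        conc[a] = pi[l, a] * r
                    lr -= _log_dirichlet(P[k, l], conc, nl)
                # proposal asymmetry
                for a in range(nl):
                    conc[a] = piprop[a] * c0 + 0.01
                lr += _log_dirichlet(pi[l], conc, nl)
                for a in range(nl):
                    conc[a] = pi[l, a] * c0 + 0.01
                lr -= _log_dirichlet(piprop, conc, nl)
                if math.log(np.random.random() + 1e-300) < lr:
                    for a in range(nl):
                        pi[l, a] = piprop[a]

        # admixture hyperparameter alpha ~ Uniform(0, alpha_max)
        if K > 1:
            aprop = alpha + np.random.normal(0.0, 0.05)
            if 0.0 < aprop < alpha_max:
                slq = 0.0
                for i in range(N):
                    for k in range(K):
                        slq += math.log(max(Q[i, k], 1e-300))
                lr = N * (math.lgamma(K * aprop) - K * math.lgamma(aprop)
                          - math.lgamma(K * alpha) + K * math.lgamma(alpha))
                lr += (aprop - alpha) * slq
                if math.log(np.random.random() + 1e-300) < lr:
                    alpha = aprop

        if sw >= burn:
            Qsum += Q
            Psum += P
            pisum += pi
            for k in range(K):
                Fsum[k] += F[k]
            alphasum += alpha

    inv = 1.0 / sweeps
    return (Qsum * inv, Psum * inv, pisum * inv, Fsum * inv, alphasum * inv,
            trace, empty_sweeps / totsweeps)


@njit(cache=True)
def newhybrids_gibbs(codes, n_alleles, z_init, burn, sweeps, seed):
    """Gibbs sampler for the six-category hybrid classification model.

    Categories: 0 P1, 1 P2, 2 F1, 3 F2, 4 BC1, 5 BC2.  ``z_init`` gives
    starting categories (anchors the parental gene pools).  Returns the
    N x 6 posterior category frequencies and posterior-mean parental
    allele frequencies."""
    np.random.seed(seed)
    N, L, _ = codes.shape
    Amax = int(n_alleles.max())
    NCAT = 6
    # expected gene-origin-pair proportions (both-P1, one-each, both-P2)
    phi = np.array([
        [1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 1.0, 0.0],
        [0.25, 0.5, 0.25],
        [0.5, 0.5, 0.0],
        [0.0, 0.5, 0.5],
    ])

    # parental frequencies initialised from copies of the anchored parents
    p = np.zeros((2, L, Amax))
    for i in range(N):
        pool = -1
        if z_init[i] == 0:
            pool = 0
        elif z_init[i] == 1:
            pool = 1
        if pool < 0:
            continue
        for l in range(L):
            for c in range(2):
                x = codes[i, l, c]
                if x >= 0:
                    p[pool, l, x] += 1.0
    for pool in range(2):
        for l in range(L):
            tot = 0.0
            for a in range(n_alleles[l]):
                tot += p[pool, l, a]
            for a in range(n_alleles[l]):
                p[pool, l, a] = (p[pool, l, a] + 1.0) / (tot + n_alleles[l])

    z = z_init.copy()
    mix = np.full(NCAT, 1.0 / NCAT)
    zcount = np.zeros((N, NCAT))
    acc_cnt = np.zeros((2, L, Amax))
    conc = np.empty(Amax)
    logw = np.empty(NCAT)
    w3 = np.empty(3)
    mixconc = np.empty(NCAT)
    psum = np.zeros((2, L, Amax))

    for sw in range(burn + sweeps):
        for a0 in range(2):
            for l in range(L):
                for a in range(Amax):
                    acc_cnt[a0, l, a] = 0.0
        catn = np.zeros(NCAT)
        for i in range(N):
            # category posterior: sum over per-locus origin classes
            for ccat in range(NCAT):
                logw[ccat] = math.log(max(mix[ccat], 1e-300))
            for l in range(L):
                x1 = codes[i, l, 0]
                x2 = codes[i, l, 1]
                if x1 < 0 or x2 < 0:
                    continue
                l0 = p[0, l, x1] * p[0, l, x2]
                l2 = p[1, l, x1] * p[1, l, x2]
                l1 = 0.5 * (p[0, l, x1] * p[1, l, x2] + p[1, l, x1] * p[0, l, x2])
                for ccat in range(NCAT):
                    lik = phi[ccat, 0] * l0 + phi[ccat, 1] * l1 + phi[ccat, 2] * l2
                    logw[ccat] += math.log(max(lik, 1e-300))
            mx = logw[0]
            for ccat in range(1, NCAT):
                if logw[ccat] > mx:
                    mx = logw[ccat]
            tot = 0.0
            for ccat in range(NCAT):
                logw[ccat] = math.exp(logw[ccat] - mx)
                tot += logw[ccat]
            u = np.random.random() * tot
            acc = 0.0
            zi = NCAT - 1
            for ccat in range(NCAT):
                acc += logw[ccat]
                if u <= acc:
                    zi = ccat
                    break
            z[i] = zi
            catn[zi] += 1.0
            if sw >= burn:
                zcount[i, zi] += 1.0

            # per-locus gene-origin pairs given the category
            for l in range(L):
                x1 = codes[i, l, 0]
                x2 = codes[i, l, 1]
                if x1 < 0 or x2 < 0:
                    continue
                l0 = p[0, l, x1] * p[0, l, x2]
                l2 = p[1, l, x1] * p[1, l, x2]
                l1a = p[0, l, x1] * p[1, l, x2]
                l1b = p[1, l, x1] * p[0, l, x2]
                w3[0] = phi[zi, 0] * l0
                w3[1] = phi[zi, 1] * 0.5 * (l1a + l1b)
                w3[2] = phi[zi, 2] * l2
                tot = w3[0] + w3[1] + w3[2]
                if tot <= 0.0:
                    continue
                u = np.random.random() * tot
                if u <= w3[0]:
                    acc_cnt[0, l, x1] += 1.0
                    acc_cnt[0, l, x2] += 1.0
                elif u <= w3[0] + w3[1]:
                    if np.random.random() * (l1a + l1b) <= l1a:
                        acc_cnt[0, l, x1] += 1.0
                        acc_cnt[1, l, x2] += 1.0
                    else:
                        acc_cnt[1, l, x1] += 1.0
                        acc_cnt[0, l, x2] += 1.0
                else:
                    acc_cnt[1, l, x1] += 1.0
                    acc_cnt[1, l, x2] += 1.0

        # parental allele frequencies ~ Dirichlet(1 + counts)
        for pool in range(2):
            for l in range(L):
                for a in range(n_alleles[l]):
                    conc[a] = 1.0 + acc_cnt[pool, l, a]
                _dirichlet_inplace(conc, n_alleles[l], p[pool, l])

        # mixing proportions ~ Dirichlet(1 + counts)
        for ccat in range(NCAT):
            mixconc[ccat] = 1.0 + catn[ccat]
        _dirichlet_inplace(mixconc, NCAT, mix)

        if sw >= burn:
            psum += p

    return zcount / sweeps, psum / sweeps


@njit(cache=True)
def ld_gtest_perm(g1, g2, n_perm, seed, group):
    """Permutation G-test of association between two single-locus genotype
    vectors (integer codes, -1 = untyped).  One locus is permuted among
    individuals within each ``group`` label.  Returns (G_obs, p)."""
    np.random.seed(seed)
    n = g1.shape[0]
    keep = np.empty(n, dtype=np.int64)
    m = 0
    for i in range(n):
        if g1[i] >= 0 and g2[i] >= 0:
            keep[m] = i
            m += 1
    if m < 2:
        return np.nan, np.nan
    a = np.empty(m, dtype=np.int64)
    b = np.empty(m, dtype=np.int64)
    grp = np.empty(m, dtype=np.int64)
    for t in range(m):
        a[t] = g1[keep[t]]
        b[t] = g2[keep[t]]
        grp[t] = group[keep[t]]
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    if ka < 2 or kb < 2:
        return np.nan, np.nan

    # margins are invariant under within-group permutation of one locus, so
    # G = 2 (sum O log O - sum O log E) compares like sum O log O alone
    ra = np.zeros(ka)
    cb = np.zeros(kb)
    for t in range(m):
        ra[a[t]] += 1.0
        cb[b[t]] += 1.0

    tab = np.zeros(ka * kb)
    touched = np.empty(m, dtype=np.int64)

    def olog(a, b, m, tab, touched):
        ntouch = 0
        for t in range(m):
            code = a[t] * kb + b[t]
            tab[code] += 1.0
            if tab[code] == 1.0:
                touched[ntouch] = code
                ntouch += 1
        s = 0.0
        for t in range(ntouch):
            o = tab[touched[t]]
            s += o * math.log(o)
            tab[touched[t]] = 0.0
        return s

    s_obs = olog(a, b, m, tab, touched)
    log_e_sum = 0.0
    for t in range(m):
        log_e_sum += math.log(ra[a[t]] * cb[b[t]] / m)
    g_obs = 2.0 * (s_obs - log_e_sum)
    # positions sorted by group: within-group blocks for the shuffle
    order = np.argsort(grp, kind="mergesort")
    gstart = np.empty(m + 1, dtype=np.int64)
    nblocks = 0
    gstart[0] = 0
    for t in range(1, m):
        if grp[order[t]] != grp[order[t - 1]]:
            nblocks += 1
            gstart[nblocks] = t
    nblocks += 1
    gstart[nblocks] = m

    bperm = b.copy()
    worse = 0
    for _ in range(n_perm):
        for blk in range(nblocks):
            lo = gstart[blk]
            hi = gstart[blk + 1]
            for t in range(hi - 1, lo, -1):
                j = lo + int(np.random.random() * (t - lo + 1))
                pt = order[t]
                pj = order[j]
                tmp = bperm[pt]
                bperm[pt] = bperm[pj]
                bperm[pj] = tmp
        sp = olog(a, bperm, m, tab, touched)
        if sp >= s_obs - 1e-12:
            worse += 1
    p = (worse + 1.0) / (n_perm + 1.0)
    return g_obs, p


@njit(cache=True)
def amova_ss(D2, pop_of, group_of, n_pops, n_groups):
    """Sums of squared distances for a two-factor nested AMOVA.

    ``D2`` is the full N x N squared-distance matrix.  Returns
    (SSD_total, SSD_within_group_sum, SSD_within_pop_sum) using
    SSD(set) = sum_{i<j in set} D2_ij / |set|.
    """
    n = D2.shape[0]
    tot = 0.0
    wg = np.zeros(n_groups)
    wp = np.zeros(n_pops)
    ng = np.zeros(n_groups)
    np_ = np.zeros(n_pops)
    for i in range(n):
        ng[group_of[i]] += 1.0
        np_[pop_of[i]] += 1.0
    for i in range(n):
        gi = group_of[i]
        pi = pop_of[i]
        for j in range(i + 1, n):
            d = D2[i, j]
            tot += d
            if group_of[j] == gi:
                wg[gi] += d
                if pop_of[j] == pi:
                    wp[pi] += d
    ssd_total = tot / n
    ssd_wg = 0.0
    for g in range(n_groups):
        if ng[g] > 0:
            ssd_wg += wg[g] / ng[g]
    ssd_wp = 0.0
    for p in range(n_pops):
        if np_[p] > 0:
            ssd_wp += wp[p] / np_[p]
    return ssd_total, ssd_wg, ssd_wp
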