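"""Discriminant analysis of principal components (DAPC).

Assumption-free counterpart to the Bayesian clustering: genotypes are
encoded as allele counts (0/1/2 per allele column, mean-imputed for
missing loci), compressed by PCA, groups are discovered by k-means on the
PC scores with a BIC criterion, and individuals are assigned by linear
discriminant analysis with Gaussian class-conditional posteriors (pooled
covariance).  No Hardy-Weinberg or linkage assumptions are made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class EncodedGenotypes:
    """N x sum(A_l) centered allele-count table."""

    X: np.ndarray  # centered counts
    column_locus: np.ndarray  # locus index per column
    column_allele: np.ndarray  # allele code per column
    center: np.ndarray
    scale: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]


@dataclass
class DapcModel:
    """Fitted DAPC: retained PCs, discriminant functions, memberships."""

    n_pcs: int
    pc_loadings: np.ndarray
    discriminants: np.ndarray  # N x n_df discriminant coordinates
    posterior: np.ndarray  # N x K membership probabilities
    labels: np.ndarray  # argmax posterior

    @property
    def K(self) -> int:
        return self.posterior.shape[1]


def encode_alleles(gm: GenotypeMatrix, scale: bool = False) -> EncodedGenotypes:
    """Allele-count encoding with mean imputation of missing loci.

    A missing locus contributes twice the overall allele frequencies, so
    every individual's row still sums to 2 per locus.
    """
    cols: list[np.ndarray] = []
    col_locus: list[int] = []
    col_allele: list[int] = []
    for l in range(gm.n_loci):
        typed = ~gm.missing_mask[:, l]
        vals = np.unique(gm.alleles[typed, l, :])
        if vals.size == 0:
            continue
        counts = np.zeros((gm.n_individuals, vals.size))
        for j, v in enumerate(vals):
            counts[:, j] = (gm.alleles[:, l, :] == v).sum(axis=1)
        freq = counts[typed].sum(axis=0)
        freq = freq / freq.sum()
        counts[~typed] = 2.0 * freq
        cols.append(counts)
        col_locus.extend([l] * vals.size)
        col_allele.extend(int(v) for v in vals)
    if not cols:
        raise ValueError("no typed locus to encode")
    X = np.hstack(cols)
    center = X.mean(axis=0)
    X = X - center
    if X.std() == 0:
        raise ValueError("monomorphic data: no variance to analyse")
    scale_vec = None
    if scale:
        scale_vec = X.std(axis=0)
        scale_vec[scale_vec == 0] = 1.0
        X = X / scale_vec
    return EncodedGenotypes(X, np.array(col_locus), np.array(col_allele), center, scale_vec)


def _pca_scores(enc: EncodedGenotypes, n_pcs: int):
    n_pcs = int(min(n_pcs, min(enc.X.shape) - 1)) or 1
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(enc.X)
    return scores, pca


def default_n_pcs(enc: EncodedGenotypes, var_target: float = 0.90) -> int:
    """Smallest PC count explaining >= ``var_target`` variance, capped at
    N/3 (an overfitting guard)."""
    scores, pca = _pca_scores(enc, min(enc.X.shape) - 1)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_target) + 1)
    cap = max(1, enc.n_individuals // 3)
    return max(1, min(k, cap, scores.shape[1]))


def find_clusters_kmeans(enc: EncodedGenotypes, k_max: int, n_pcs: int | None = None,
                         seed: int = 0):
    """k-means group discovery on PC scores for K = 1..k_max.

    BIC(K) = n ln(WSS_K / n) + K ln(n); returns a dict with per-K labels,
    the BIC curve and the BIC-minimizing K.  K > N is skipped with a
    warning.  Deterministic under ``seed`` (k-means++, 10 restarts).

    By default all PCs are retained for group discovery (dimension
    reduction is only needed for the discriminant step); on unstructured
    data the BIC curve is then nearly flat, while real clusters produce a
    pronounced minimum at the true K.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if n_pcs is None:
        n_pcs = min(enc.X.shape) - 1  # retain (almost) everything
    scores, _ = _pca_scores(enc, n_pcs)
    n = scores.shape[0]
    labels_by_k: dict[int, np.ndarray] = {}
    bic: dict[int, float] = {}
    for K in range(1, k_max + 1):
        if K > n:
            logger.warning("skipping K=%d > N=%d", K, n)
            continue
        if K == 1:
            lab = np.zeros(n, dtype=np.int64)
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=K, n_init=10, random_state=seed)
            lab = km.fit_predict(scores)
            wss = float(km.inertia_)
        wss = max(wss, 1e-12)  # guard the K == N degenerate fit
        labels_by_k[K] = lab
        bic[K] = n * np.log(wss / n) + K * np.log(n)
    best_k = min(bic, key=bic.get)
    return {"labels_by_k": labels_by_k, "bic": bic, "best_k": best_k,
            "best_labels": labels_by_k[best_k], "n_pcs": n_pcs}


def dapc_assign(enc: EncodedGenotypes, labels: np.ndarray, n_pcs: int | None = None) -> DapcModel:
    """Linear discriminant assignment of individuals to given groups.

    Posterior memberships are Gaussian class-conditionals with pooled
    covariance on the retained PCs; a tiny ridge is added if the pooled
    covariance is singular.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    K = uniq.size
    if K == 1:
        n = enc.n_individuals
        return DapcModel(0, np.empty((0, enc.X.shape[1])), np.zeros((n, 0)),
                         np.ones((n, 1)), np.zeros(n, dtype=np.int64))
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    if n_pcs is None:
        n_pcs = default_n_pcs(enc)
    scores, pca = _pca_scores(enc, n_pcs)
    lda = LinearDiscriminantAnalysis(solver="svd", store_covariance=False)
    try:
        lda.fit(scores, labels)
    except np.linalg.LinAlgError:  # pragma: no cover - singular pooled covariance
        logger.warning("singular pooled covariance; adding ridge 1e-8")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-8)
        lda.fit(scores, labels)
    post = lda.predict_proba(scores)
    try:
        disc = lda.transform(scores)
    except Exception:
        disc = np.zeros((scores.shape[0], 0))
    hard = uniq[np.argmax(post, axis=1)]
    return DapcModel(scores.shape[1], pca.components_, disc, post, hard)
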