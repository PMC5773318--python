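"""Nested lineage delimitation: the "Russian-doll" engine.

Combines the two clustering routes (Bayesian admixture, DAPC) into a
decision procedure for the number of genetic groups K and a recursive
splitter producing a nested partition tree:

1. *Threshold assignment*: an individual is "pure" in cluster k iff its
   assignment probability exceeds tau_pure (default 0.75) in **every**
   replicate chain; otherwise it is admixed over the clusters whose mean
   probability exceeds tau_comp (default 0.1 — anything below is noise).
2. *Method discordance*: among individuals confidently assigned by both
   methods, the mismatch fraction after Hungarian label matching.
3. *Congruence criterion for K*: the accepted K is the highest for which
   all four (method x scope) combinations agree — admixture vs DAPC on the
   full sample, and, within each child of the previously accepted
   partition, the subset reruns either find no further split or map
   one-to-one onto the full-sample clusters, every comparison staying
   within tau_disc discordance.
4. *Recursive splitting*: apply the criterion at the root, exclude each
   node's admixed individuals, recurse into the children until K = 1 or
   the node is too small to split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .admixture import AlignedRuns, ChainConfig, run_replicates
from .dapc import dapc_assign, encode_alleles, find_clusters_kmeans
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssignmentDecision:
    """Per-individual verdict from the replicate-threshold rule."""

    index: int
    status: str  # 'pure' | 'admixed' | 'unassignable'
    pure_cluster: int | None
    admixed_set: tuple[int, ...]
    mean_q: np.ndarray
    per_run_q: np.ndarray  # n_runs x K


@dataclass
class DelimitConfig:
    """Knobs of the delimitation engine."""

    chain: ChainConfig = field(default_factory=lambda: ChainConfig(n_chains=3))
    tau_pure: float = 0.75
    tau_comp: float = 0.1
    tau_disc: float = 0.05
    tau_rep: float = 0.05  # max pairwise mean |dQ| across aligned replicates
    k_max: int = 4
    min_node: int = 10
    n_pcs: int | None = None
    seed: int = 0


@dataclass
class PartitionNode:
    """A node of the nested partition tree."""

    name: str
    level: int
    members: np.ndarray  # global individual indices
    accepted_k: int = 1
    children: list["PartitionNode"] = field(default_factory=list)
    excluded_admixed: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    discordance: float = np.nan
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PartitionTree:
    root: PartitionNode
    individual_ids: list[str]

    def leaves(self) -> list[PartitionNode]:
        out: list[PartitionNode] = []

        def walk(n: PartitionNode):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[PartitionNode]:
        out: list[PartitionNode] = []

        def walk(n: PartitionNode):
            if not n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def excluded(self) -> np.ndarray:
        out: list[np.ndarray] = []

        def walk(n: PartitionNode):
            out.append(n.excluded_admixed)
            for c in n.children:
                walk(c)

        walk(self.root)
        return np.concatenate(out) if out else np.array([], dtype=np.int64)

    def leaf_labels(self) -> np.ndarray:
        """Leaf index per individual; -1 for individuals excluded as admixed."""
        lab = np.full(len(self.individual_ids), -1, dtype=np.int64)
        for j, leaf in enumerate(self.leaves()):
            lab[leaf.members] = j
        return lab

    def to_json(self) -> str:
        def node_dict(n: PartitionNode):
            return {
                "name": n.name,
                "level": n.level,
                "accepted_k": n.accepted_k,
                "n_members": int(n.members.size),
                "members": [self.individual_ids[i] for i in n.members],
                "excluded_admixed": [self.individual_ids[i] for i in n.excluded_admixed],
                "discordance": None if np.isnan(n.discordance) else float(n.discordance),
                "children": [node_dict(c) for c in n.children],
            }

        return json.dumps(node_dict(self.root), indent=1)


# ---------------------------------------------------------------------------
# threshold assignment and discordance
# ---------------------------------------------------------------------------


def threshold_assign(aligned: AlignedRuns, tau_pure: float = 0.75,
                     tau_comp: float = 0.1) -> list[AssignmentDecision]:
    """Apply the replicate-threshold rule to aligned Q matrices.

    Pure in k iff q_ik > tau_pure in every run (strict inequality);
    otherwise admixed over {k : mean q_ik > tau_comp}; unassignable when
    no component clears tau_comp.
    """
    qs = np.stack([r.Q for r in aligned.runs])  # R x N x K
    mean_q = aligned.mean_Q
    out: list[AssignmentDecision] = []
    for i in range(mean_q.shape[0]):
        pure_k = np.where((qs[:, i, :] > tau_pure).all(axis=0))[0]
        if pure_k.size:
            out.append(AssignmentDecision(i, "pure", int(pure_k[0]), (), mean_q[i], qs[:, i, :]))
            continue
        comp = tuple(int(k) for k in np.where(mean_q[i] > tau_comp)[0])
        status = "admixed" if comp else "unassignable"
        out.append(AssignmentDecision(i, status, None, comp, mean_q[i], qs[:, i, :]))
    return out


def pure_labels(decisions: list[AssignmentDecision], n: int) -> np.ndarray:
    """Label vector with the pure cluster, -1 for admixed/unassignable."""
    lab = np.full(n, -1, dtype=np.int64)
    for d in decisions:
        if d.status == "pure":
            lab[d.index] = d.pure_cluster
    return lab


def replicate_agreement(aligned: AlignedRuns) -> float:
    """Fraction of individuals whose per-run argmax cluster is identical
    across all aligned runs (a chain-convergence diagnostic)."""
    argmaxes = np.stack([r.Q.argmax(axis=1) for r in aligned.runs])
    return float((argmaxes == argmaxes[0]).all(axis=0).mean())


def method_discordance(labels_a, labels_b, eligible=None):
    """Mismatch fraction between two labelings after Hungarian matching.

    ``eligible`` restricts the comparison (default: individuals labelled
    >= 0 by both).  Returns ``(fraction, mapping)`` where ``mapping`` sends
    labels of ``b`` onto labels of ``a``.  The two labelings must use the
    same number of clusters.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if eligible is None:
        eligible = np.where((labels_a >= 0) & (labels_b >= 0))[0]
    else:
        eligible = np.asarray(eligible)
    a = labels_a[eligible]
    b = labels_b[eligible]
    ka = np.unique(a)
    kb = np.unique(b)
    if ka.size != kb.size:
        raise ValueError(f"labelings use different K ({ka.size} vs {kb.size})")
    amap = {v: i for i, v in enumerate(ka)}
    bmap = {v: i for i, v in enumerate(kb)}
    K = ka.size
    conf = np.zeros((K, K))
    for x, y in zip(a, b):
        conf[amap[x], bmap[y]] += 1
    row, col = linear_sum_assignment(-conf)
    matched = conf[row, col].sum()
    frac = float(1.0 - matched / max(len(a), 1))
    mapping = {int(kb[c]): int(ka[r]) for r, c in zip(row, col)}
    return frac, mapping


# ---------------------------------------------------------------------------
# congruence criterion for K
# ---------------------------------------------------------------------------


@dataclass
class _MethodLabels:
    """Confident labels from both methods on one sample (local indices)."""

    adm: np.ndarray  # -1 = not pure
    dapc: np.ndarray  # -1 = not confident
    decisions: list[AssignmentDecision]
    replicate_agreement: float
    replicate_dq: float  # max pairwise mean |dQ| after alignment


def replicate_dq(aligned: AlignedRuns) -> float:
    """Largest pairwise mean absolute Q difference between aligned runs.

    Replicate chains that found the same posterior mode stay well below
    0.05; chains stuck in different modes differ by O(1) for a whole block
    of individuals.  Used as the chain-coherence gate of the congruence
    criterion: a K whose replicate runs disagree cannot support identical
    individual assignments across runs.
    """
    qs = [r.Q for r in aligned.runs]
    worst = 0.0
    for i in range(len(qs)):
        for j in range(i + 1, len(qs)):
            worst = max(worst, float(np.abs(qs[i] - qs[j]).mean()))
    return worst


def _run_methods(gm_sub: GenotypeMatrix, K: int, cfg: DelimitConfig, seed_salt: int) -> _MethodLabels:
    chain_cfg = replace(cfg.chain, K=K, seed=(cfg.seed + cfg.chain.seed + seed_salt) % (2**31 - 1))
    aligned = run_replicates(gm_sub, chain_cfg)
    decisions = threshold_assign(aligned, cfg.tau_pure, cfg.tau_comp)
    adm = pure_labels(decisions, gm_sub.n_individuals)
    agree = replicate_agreement(aligned)
    dq = replicate_dq(aligned)

    enc = encode_alleles(gm_sub)
    km = find_clusters_kmeans(enc, k_max=K, n_pcs=cfg.n_pcs, seed=chain_cfg.seed % (2**31 - 1))
    model = dapc_assign(enc, km["labels_by_k"][K], n_pcs=cfg.n_pcs)
    dap = np.where(model.posterior.max(axis=1) > cfg.tau_pure, model.labels, -1)
    return _MethodLabels(adm, dap, decisions, agree, dq)


def _clusters_well_occupied(labels: np.ndarray, K: int, min_node: int) -> bool:
    counts = np.bincount(labels[labels >= 0], minlength=K)
    return counts.size == K and bool((counts >= min_node).all())


def _pair_congruent(labels_a, labels_b, tau_disc, min_node) -> tuple[bool, float]:
    eligible = np.where((labels_a >= 0) & (labels_b >= 0))[0]
    if eligible.size == 0:
        return False, 1.0
    try:
        frac, _ = method_discordance(labels_a, labels_b, eligible)
    except ValueError:
        return False, 1.0
    return frac <= tau_disc, frac


def congruent_k(gm: GenotypeMatrix, members, cfg: DelimitConfig, k_max: int | None = None,
                seed_salt: int = 0):
    """Choose the number of groups by cross-method / cross-subset congruence.

    Returns ``(accepted_k, labels, diagnostics)`` where ``labels`` (local
    to ``members``) hold the pure cluster under the accepted K, -1 for
    admixed.  Accepted K is the highest congruent K (1 if none).
    """
    members = np.asarray(members, dtype=np.int64)
    k_max = cfg.k_max if k_max is None else k_max
    n = members.size
    diagnostics: dict = {"evaluated": {}}
    if n < max(10, 2 * cfg.min_node):
        return 1, np.zeros(n, dtype=np.int64), diagnostics

    gm_sub = gm.subset(members)
    accepted_k = 1
    accepted_labels = np.zeros(n, dtype=np.int64)
    accepted_children: list[np.ndarray] = [np.arange(n)]
    accepted_disc = np.nan

    for K in range(2, k_max + 1):
        if K > n:
            break
        salt = seed_salt + 1_000_003 * K
        full = _run_methods(gm_sub, K, cfg, salt)
        entry: dict = {
            "replicate_agreement": full.replicate_agreement,
            "replicate_dq": full.replicate_dq,
        }
        ok = (
            full.replicate_dq <= cfg.tau_rep
            and _clusters_well_occupied(full.adm, K, cfg.min_node)
            and _clusters_well_occupied(full.dapc, K, cfg.min_node)
        )
        disc = np.nan
        if ok:
            ok, disc = _pair_congruent(full.adm, full.dapc, cfg.tau_disc, cfg.min_node)
        entry["full_discordance"] = disc
        if ok:
            ok = _subsets_congruent(gm_sub, full, accepted_children, cfg, salt, entry)
        entry["congruent"] = ok
        diagnostics["evaluated"][K] = entry
        if ok:
            accepted_k = K
            accepted_labels = full.adm.copy()
            accepted_children = [np.where(full.adm == k)[0] for k in range(K)]
            accepted_disc = disc
    diagnostics["accepted_k"] = accepted_k
    diagnostics["discordance"] = accepted_disc
    return accepted_k, accepted_labels, diagnostics


def _subsets_congruent(gm_sub, full: _MethodLabels, children: list[np.ndarray],
                       cfg: DelimitConfig, salt: int, entry: dict) -> bool:
    """Check the subset half of the four-combination criterion.

    ``children`` come from the previously accepted partition; within every
    child that the candidate K subdivides, both methods are rerun at the
    child's cluster count and must map one-to-one onto the full-sample
    clusters (within tau_disc, with coherent replicate chains).  A child
    the candidate keeps whole imposes no constraint here: deeper structure
    inside it is the recursion's job, not grounds to reject K.  A single
    child covering the whole node is the full sample again — trivially
    congruent with itself.
    """
    if len(children) == 1 and children[0].size == gm_sub.n_individuals:
        return True
    subset_diag = []
    for ci, child in enumerate(children):
        if child.size < 2 * cfg.min_node:
            logger.info("child %d too small to re-analyse (%d members)", ci, child.size)
            continue
        full_adm_child = full.adm[child]
        counts = np.bincount(full_adm_child[full_adm_child >= 0],
                             minlength=max(full.adm.max() + 1, 1))
        present = np.where(counts >= cfg.min_node)[0]
        k_c = present.size
        if k_c == 0:
            subset_diag.append((ci, 0, "dissolved"))
            entry["subset"] = subset_diag
            return False  # the child dissolved into admixture at this K
        if k_c == 1:
            subset_diag.append((ci, 1, "kept_whole"))
            continue
        sub = gm_sub.subset(child)
        res = _run_methods(sub, k_c, cfg, salt + 77_777 * (ci + 1))
        if res.replicate_dq > cfg.tau_rep:
            subset_diag.append((ci, k_c, "subset_incoherent"))
            entry["subset"] = subset_diag
            return False
        # full labels restricted to this child, keeping only its clusters
        restr_adm = np.where(np.isin(full_adm_child, present), full_adm_child, -1)
        checks = [
            _pair_congruent(res.adm, res.dapc, cfg.tau_disc, cfg.min_node),
            _pair_congruent(res.adm, restr_adm, cfg.tau_disc, cfg.min_node),
            _pair_congruent(res.dapc, restr_adm, cfg.tau_disc, cfg.min_node),
        ]
        if not (_clusters_well_occupied(res.adm, k_c, cfg.min_node)
                and _clusters_well_occupied(res.dapc, k_c, cfg.min_node)
                and all(ok for ok, _ in checks)):
            subset_diag.append((ci, k_c, "mismatch"))
            entry["subset"] = subset_diag
            return False
        subset_diag.append((ci, k_c, "ok"))
    entry["subset"] = subset_diag
    return True


# ---------------------------------------------------------------------------
# the recursive splitter
# ---------------------------------------------------------------------------

_LEVEL_NAMES = {0: "root", 1: "lineage", 2: "cluster"}


def russian_doll(gm: GenotypeMatrix, cfg: DelimitConfig, max_depth: int = 6) -> PartitionTree:
    """Recursively delimit nested groups; returns the partition tree.

    At each node the congruence criterion picks K; the node's admixed
    individuals are recorded and excluded, and each child is re-analysed
    until K = 1 or fewer than ``2 * min_node`` members remain.
    """
    counter = {"n": 0}

    def build(members: np.ndarray, name: str, level: int) -> PartitionNode:
        counter["n"] += 1
        salt = 7_919 * counter["n"]
        node = PartitionNode(name=name, level=level, members=members)
        if level >= max_depth or members.size < 2 * cfg.min_node:
            return node
        k, labels, diag = congruent_k(gm, members, cfg, seed_salt=salt)
        node.accepted_k = k
        node.diagnostics = diag
        node.discordance = diag.get("discordance", np.nan)
        if k == 1:
            return node
        node.excluded_admixed = members[labels < 0]
        for c in range(k):
            child_members = members[labels == c]
            child = build(child_members, f"{name}.{c + 1}", level + 1)
            node.children.append(child)
        return node

    root = build(np.arange(gm.n_individuals), "root", 0)
    tree = PartitionTree(root, list(gm.individual_ids))
    logger.info(
        "russian_doll: %d internal nodes, %d leaves, %d admixed excluded",
        len(tree.internal_nodes()), len(tree.leaves()), tree.excluded().size,
    )
    return tree
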