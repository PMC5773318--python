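"""End-to-end pipeline: read -> clones -> delimit -> stats -> hybrids -> network.

One declarative config drives the whole analysis and a structured report
is emitted: the nested partition tree, per-individual decisions, pairwise
F_ST / D_est matrices per level, per-locus global F_ST, the hierarchical
AMOVA, linkage-disequilibrium tests, hybrid classifications and the
minimum-spanning-tree edge list — the table shapes of a complete
lineage-delimitation study.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import ChainConfig
from .clones import identify_mlg
from .delimit import DelimitConfig, PartitionTree, russian_doll
from .genotypes import GenotypeMatrix, SampleHierarchy, read_genotypes, summarize_missing
from .hybrids import classify_hybrids
from .network import cross_cluster_edge_fraction, das_matrix, minimum_spanning_tree
from .simulate import SimConfig, simulate_hierarchy
from .stats import allele_stats, amova, genotypic_ld, jost_dest, per_locus_global_fst, wc_fst

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    input_path: str | None = None
    input_format: str = "genepop"
    metadata_path: str | None = None
    simulate: SimConfig | None = None  # used when input_path is None
    clone_policy: str = "strict"
    delimit: DelimitConfig = field(default_factory=DelimitConfig)
    hybrid_chain: ChainConfig = field(default_factory=lambda: ChainConfig(
        burn_in=2_000, n_sweeps=20_000, n_chains=1))
    n_perm_fst: int = 199
    n_perm_amova: int = 199
    n_perm_ld: int = 5_000
    run_hybrids: bool = True
    run_network: bool = True
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "tree_spec" in sim:
                sim["tree_spec"] = tuple(sim["tree_spec"])
            raw["simulate"] = SimConfig(**sim)
        if "delimit" in raw and raw["delimit"] is not None:
            d = dict(raw["delimit"])
            if "chain" in d:
                d["chain"] = ChainConfig(**d["chain"])
            raw["delimit"] = DelimitConfig(**d)
        if "hybrid_chain" in raw and raw["hybrid_chain"] is not None:
            raw["hybrid_chain"] = ChainConfig(**raw["hybrid_chain"])
        return cls(**raw)


def _tree_groups(tree: PartitionTree) -> dict:
    """Group index dictionaries at the two delimited levels."""
    level1 = {c.name: c.members for c in tree.root.children} or {
        tree.root.name: tree.root.members
    }
    leaves = {lf.name: lf.members for lf in tree.leaves()}
    return {"level1": level1, "leaves": leaves}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the result bundle (and writes artifacts
    when ``cfg.out_dir`` is set)."""
    t0 = time.time()
    timings: dict[str, float] = {}
    results: dict = {"config": cfg}

    # ---- input -----------------------------------------------------------
    if cfg.input_path is not None:
        gm, hier = read_genotypes(cfg.input_path, cfg.input_format, cfg.metadata_path)
        truth = None
    else:
        sim = cfg.simulate or SimConfig(seed=cfg.seed)
        gm, hier, truth = simulate_hierarchy(sim)
    results["genotypes"], results["hierarchy"], results["truth"] = gm, hier, truth
    per_ind_missing, _ = summarize_missing(gm)
    timings["input"] = time.time() - t0

    # ---- clone screening -------------------------------------------------
    t = time.time()
    mlg = identify_mlg(gm, cfg.clone_policy)
    keep_ids = set(mlg.representatives.values())
    keep_idx = [i for i, ind in enumerate(gm.individual_ids) if ind in keep_ids]
    gm_u = gm.subset(keep_idx)
    hier_u = hier.subset(keep_idx)
    results["mlg"] = mlg
    results["genotypes_unique"], results["hierarchy_unique"] = gm_u, hier_u
    results["n_clones_removed"] = gm.n_individuals - gm_u.n_individuals
    timings["clones"] = time.time() - t

    # ---- nested delimitation ---------------------------------------------
    t = time.time()
    dcfg = replace(cfg.delimit, seed=cfg.delimit.seed + cfg.seed)
    tree = russian_doll(gm_u, dcfg)
    results["tree"] = tree
    timings["delimit"] = time.time() - t

    groups = _tree_groups(tree)
    leaf_groups = groups["leaves"]
    lvl1_groups = groups["level1"]

    # ---- differentiation statistics --------------------------------------
    t = time.time()
    stats_out: dict = {}
    if len(lvl1_groups) >= 2:
        stats_out["fst_level1"], stats_out["fst_level1_p"] = wc_fst(
            gm_u, lvl1_groups, cfg.n_perm_fst, cfg.seed + 11)
        stats_out["dest_level1"], stats_out["dest_level1_p"] = jost_dest(
            gm_u, lvl1_groups, cfg.n_perm_fst, cfg.seed + 13)
        stats_out["per_locus_fst"] = per_locus_global_fst(gm_u, lvl1_groups)
        stats_out["allele_stats"] = allele_stats(gm_u, lvl1_groups)
    if len(leaf_groups) >= 2:
        stats_out["fst_leaves"], stats_out["fst_leaves_p"] = wc_fst(
            gm_u, leaf_groups, cfg.n_perm_fst, cfg.seed + 17)
        stats_out["dest_leaves"], stats_out["dest_leaves_p"] = jost_dest(
            gm_u, leaf_groups, cfg.n_perm_fst, cfg.seed + 19)
    if gm_u.n_loci >= 2:
        stats_out["ld"] = genotypic_ld(gm_u, None, cfg.n_perm_ld, 0.05, cfg.seed + 23)
    # AMOVA with level-1 nodes as groups, leaves as populations
    amova_ok = (
        len(lvl1_groups) >= 2
        and any(not c.is_leaf for c in tree.root.children)
    )
    if amova_ok:
        leaf_lab = tree.leaf_labels()
        lvl1_of = np.full(gm_u.n_individuals, -1, dtype=np.int64)
        for g, (name, idx) in enumerate(lvl1_groups.items()):
            lvl1_of[idx] = g
        keep = np.where((leaf_lab >= 0) & (lvl1_of >= 0))[0]
        stats_out["amova"] = amova(
            gm_u.subset(keep), lvl1_of[keep], leaf_lab[keep],
            cfg.n_perm_amova, cfg.seed + 29)
    results["stats"] = stats_out
    timings["stats"] = time.time() - t

    # ---- hybrids between sibling leaves ----------------------------------
    t = time.time()
    hybrid_tables = []
    if cfg.run_hybrids:
        for node in tree.internal_nodes():
            leaf_children = [c for c in node.children if c.is_leaf]
            for i in range(len(leaf_children)):
                for j in range(i + 1, len(leaf_children)):
                    a, b = leaf_children[i], leaf_children[j]
                    cand = np.concatenate([node.excluded_admixed])
                    hp = classify_hybrids(
                        gm_u, cand, a.members, b.members,
                        replace(cfg.hybrid_chain, seed=cfg.seed + 31 * (i + 1) * (j + 2)),
                    )
                    tab = hp.posterior.copy()
                    tab["map"] = hp.map_category
                    tab["hybrid_prob"] = hp.hybrid_probability
                    tab["pair"] = f"{a.name}|{b.name}"
                    hybrid_tables.append(tab)
    results["hybrids"] = pd.concat(hybrid_tables) if hybrid_tables else pd.DataFrame()
    timings["hybrids"] = time.time() - t

    # ---- network ----------------------------------------------------------
    t = time.time()
    if cfg.run_network and gm_u.n_individuals >= 2:
        dm = das_matrix(gm_u)
        mst = minimum_spanning_tree(dm)
        leaf_lab = tree.leaf_labels()
        results["mst"] = mst
        results["mst_cross_fraction"] = cross_cluster_edge_fraction(mst, leaf_lab)
    timings["network"] = time.time() - t

    results["timings"] = timings
    results["missing_per_individual"] = per_ind_missing
    report = render_report(results)
    results["report"] = report

    if cfg.out_dir:
        _write_artifacts(cfg, results)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return results


def render_report(results: dict) -> dict:
    """Condense the result bundle into a JSON-serializable report."""
    tree: PartitionTree = results["tree"]
    gm: GenotypeMatrix = results["genotypes_unique"]
    hier: SampleHierarchy = results["hierarchy_unique"]
    leaves = tree.leaves()
    leaf_lab = tree.leaf_labels()
    excluded = tree.excluded()

    counts_per_site: dict[str, dict[str, int]] = {}
    for j, leaf in enumerate(leaves):
        for i in leaf.members:
            site = hier.site[i] if i < len(hier.site) else "NA"
            counts_per_site.setdefault(site, {})[leaf.name] = (
                counts_per_site.get(site, {}).get(leaf.name, 0) + 1
            )

    n_total = results["genotypes"].n_individuals - results["n_clones_removed"]
    pct_admixed = 100.0 * excluded.size / max(n_total, 1)
    discordances = [
        n.discordance for n in tree.internal_nodes() if np.isfinite(n.discordance)
    ]

    stats_out = results.get("stats", {})
    report: dict = {
        "n_individuals": int(results["genotypes"].n_individuals),
        "n_clones_removed": int(results["n_clones_removed"]),
        "tree": {
            "n_internal_nodes": len(tree.internal_nodes()),
            "n_leaves": len(leaves),
            "accepted_k_root": tree.root.accepted_k,
            "leaf_sizes": {lf.name: int(lf.members.size) for lf in leaves},
        },
        "admixed": {
            "n": int(excluded.size),
            "percent": pct_admixed,
        },
        "method_discordance_percent": [100 * d for d in discordances],
        "counts_per_site": counts_per_site,
    }
    if "fst_level1" in stats_out:
        report["fst_level1"] = stats_out["fst_level1"].round(4).to_dict()
        report["dest_level1"] = stats_out["dest_level1"].round(4).to_dict()
        plf = stats_out["per_locus_fst"]
        report["per_locus_fst"] = {
            "mean": plf.attrs["mean"], "se": plf.attrs["se"],
            "max": float(np.nanmax(plf["theta"].values)),
        }
    if "fst_leaves" in stats_out:
        report["fst_leaves"] = stats_out["fst_leaves"].round(4).to_dict()
        report["dest_leaves"] = stats_out["dest_leaves"].round(4).to_dict()
    if "ld" in stats_out:
        report["ld"] = {
            "n_significant": stats_out["ld"].attrs["n_significant"],
            "n_pairs": stats_out["ld"].attrs["n_pairs"],
        }
    if "amova" in stats_out:
        am = stats_out["amova"]
        pct = am.percentages
        report["amova"] = {
            "pct_among_groups": pct[0],
            "pct_among_pops_within_groups": pct[1],
            "pct_within_pops": pct[2],
            "phi_ct": am.phi_ct, "phi_sc": am.phi_sc, "phi_st": am.phi_st,
            "p_ct": am.p_ct, "p_sc": am.p_sc, "p_st": am.p_st,
        }
    hyb = results.get("hybrids")
    if hyb is not None and len(hyb):
        is_hyb = hyb["hybrid_prob"] > 0.5
        report["hybrids"] = {
            "n_tested": int(len(hyb)),
            "n_hybrids": int(is_hyb.sum()),
            "map_categories": hyb.loc[is_hyb, "map"].value_counts().to_dict(),
        }
    else:
        report["hybrids"] = {"n_tested": 0, "n_hybrids": 0, "map_categories": {}}
    if "mst_cross_fraction" in results:
        report["mst_cross_cluster_edge_fraction"] = results["mst_cross_fraction"]
    return report


def _decisions_frame(results: dict) -> pd.DataFrame:
    tree: PartitionTree = results["tree"]
    leaf_lab = tree.leaf_labels()
    leaves = tree.leaves()
    status = []
    for i, ind in enumerate(tree.individual_ids):
        if leaf_lab[i] >= 0:
            status.append((ind, leaves[leaf_lab[i]].name, "pure"))
        else:
            status.append((ind, "", "admixed"))
    return pd.DataFrame(status, columns=["individual", "leaf", "status"])


def _write_artifacts(cfg: PipelineConfig, results: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree: PartitionTree = results["tree"]
    (out / "tree.json").write_text(tree.to_json())
    _decisions_frame(results).to_csv(out / "decisions.tsv", sep="\t", index=False)
    stats_out = results.get("stats", {})
    for key, fname in [("fst_leaves", "fst.tsv"), ("dest_leaves", "dest.tsv")]:
        if key in stats_out:
            stats_out[key].to_csv(out / fname, sep="\t")
    if "amova" in stats_out:
        stats_out["amova"].to_frame().to_csv(out / "amova.tsv", sep="\t", index=False)
    if "ld" in stats_out:
        stats_out["ld"].to_csv(out / "ld.tsv", sep="\t", index=False)
    hyb = results.get("hybrids")
    if hyb is not None and len(hyb):
        hyb.to_csv(out / "hybrids.tsv", sep="\t")
    if "mst" in results:
        results["mst"].to_frame().to_csv(out / "mst.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(results["report"], indent=1, default=_json_default))
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "input": cfg.input_path or "simulated",
        "timings_s": {k: round(v, 2) for k, v in results["timings"].items()},
        "config": _config_dict(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_json_default))


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    sim = d.get("simulate")
    if sim and sim.get("site_mixtures") is not None:
        d["simulate"]["site_mixtures"] = np.asarray(sim["site_mixtures"]).tolist()
    return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def plot_membership_bars(mean_q: np.ndarray, labels=None, path=None):
    """Optional stacked-bar plot of admixture proportions (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n, k = mean_q.shape
    order = np.argsort(labels) if labels is not None else np.arange(n)
    fig, ax = plt.subplots(figsize=(max(6, n / 50), 2.5))
    bottom = np.zeros(n)
    for j in range(k):
        ax.bar(np.arange(n), mean_q[order, j], bottom=bottom, width=1.0)
        bottom += mean_q[order, j]
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("membership")
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
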