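"""End-to-end pipeline: read inputs, run the requested stages, write TSVs.

Every stage writes tab-separated tables with 6-decimal formatting and a
fixed column order so re-runs diff cleanly; all stochastic stages draw
their seeds deterministically from the single run seed, so identical
configuration + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assembly as asm
from . import diversity as dv
from . import drivers as dr
from . import networks as nw
from .io import CommunityMatrix, align_samples, rarefy, read_community, read_env, read_tree

logger = logging.getLogger("lakemicro")

ALL_STAGES = ("diversity", "drivers", "neutral", "assembly", "network")

SPATIAL_VARS = ("longitude", "latitude", "altitude")


@dataclass
class RunConfig:
    community: str
    env: str
    tree: str | None = None
    out_dir: str = "lakemicro_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    orientation: str = "otus"
    rarefy: bool = False
    relative: bool = False
    n_null: int = 999
    n_perm: int = 999
    r_threshold: float = 0.8
    p_threshold: float = 0.01
    prevalence_min: float = 1 / 3
    extra: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path, index_label="sample") -> None:
    df.to_csv(path, sep="\t", float_format="%.6f", index_label=index_label)


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(k + 1)[k].generate_state(1)[0] % (2**31 - 1))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the in-memory results bundle.

    Raises before any computation when a phylogenetic stage is requested
    without a tree.
    """
    stages = tuple(cfg.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    needs_tree = {"diversity", "assembly"} & set(stages)
    if needs_tree and cfg.tree is None:
        raise ValueError(f"stages {sorted(needs_tree)} require a tree")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = read_community(cfg.community, orientation=cfg.orientation)
    env = read_env(cfg.env)
    cm, env = align_samples(cm, env)
    if cfg.rarefy:
        cm = rarefy(cm, seed=_child_seed(cfg.seed, 0))
    tree = read_tree(cfg.tree, prune_to=cm.otu_ids) if cfg.tree else None

    bundle: dict = {"community": cm, "env": env, "tree": tree}

    if "diversity" in stages:
        alpha = dv.alpha_diversity(cm, tree)
        _write(alpha, out / "alpha_diversity.tsv")
        bc = dv.bray_curtis(cm)
        _write(bc, out / "bray_curtis.tsv")
        coords, evals, prop = dv.pcoa(bc)
        _write(coords, out / "pcoa_coordinates.tsv")
        _write(prop.to_frame("proportion_explained"), out / "pcoa_proportions.tsv",
               index_label="axis")
        r_stat, p = dv.anosim(bc, cm.groups, n_perm=cfg.n_perm,
                              seed=_child_seed(cfg.seed, 1))
        _write(pd.DataFrame([{"R": r_stat, "p": p}]), out / "anosim.tsv",
               index_label="row")
        screen = dv.spearman_screen(alpha, env)
        screen.to_csv(out / "alpha_env_spearman.tsv", sep="\t",
                      float_format="%.6f", index=False)
        bundle["alpha"] = alpha
        bundle["bray_curtis"] = bc
        bundle["anosim"] = (r_stat, p)

    if "drivers" in stages:
        water = env[[c for c in env.columns if c not in SPATIAL_VARS]]
        retained = dr.vif_filter(water)
        rda_res = dr.rda(cm, water[retained], n_perm=cfg.n_perm,
                         seed=_child_seed(cfg.seed, 2))
        _write(rda_res["scores"], out / "rda_scores.tsv")
        rda_res["factors"].to_csv(out / "rda_factors.tsv", sep="\t",
                                  float_format="%.6f", index=False)
        spatial = dr.pcnm(env[["longitude", "latitude"]])
        # keep the model identifiable: only the envfit-significant water
        # factors enter the partition (top 3 by marginal R2 as fallback)
        fac = rda_res["factors"]
        sig = list(fac.loc[fac["p"] <= 0.05, "factor"])
        if not sig:
            sig = list(fac.sort_values("r2", ascending=False)["factor"][:3])
        vpa_res = dr.vpa(cm, spatial, water[sig])
        pd.Series(vpa_res).to_frame("fraction").to_csv(
            out / "vpa_fractions.tsv", sep="\t", float_format="%.6f",
            index_label="component")
        bundle["rda"] = rda_res
        bundle["vpa"] = vpa_res
        bundle["pcnm"] = spatial
        bundle["vif_retained"] = retained

    if "neutral" in stages:
        fit = asm.fit_neutral(cm)
        fit.table.to_csv(out / "neutral_fit_otus.tsv", sep="\t",
                         float_format="%.6f", index_label="otu")
        pd.DataFrame([{"m": fit.m, "R2": fit.r2, "N_T": fit.n_t}]).to_csv(
            out / "neutral_fit.tsv", sep="\t", float_format="%.6f", index=False)
        bundle["neutral"] = fit

    if "assembly" in stages:
        bnti = asm.beta_nti(cm, tree, n_null=cfg.n_null,
                            seed=_child_seed(cfg.seed, 3))
        rc = asm.raup_crick_bray(cm, n_null=cfg.n_null,
                                 seed=_child_seed(cfg.seed, 4))
        _write(bnti, out / "beta_nti.tsv")
        _write(rc, out / "rcbray.tsv")
        res = asm.classify_processes(bnti, rc)
        res.fractions.to_frame("percent").to_csv(
            out / "process_fractions.tsv", sep="\t", float_format="%.6f",
            index_label="process")
        res.pairs.to_csv(out / "process_pairs.tsv", sep="\t",
                         float_format="%.6f", index=False)
        corr = asm.bnti_env_correlation(bnti, env, n_perm=cfg.n_perm,
                                        seed=_child_seed(cfg.seed, 5))
        corr.to_csv(out / "bnti_env_spearman.tsv", sep="\t",
                    float_format="%.6f", index=False)
        bundle["assembly"] = res
        bundle["bnti"] = bnti
        bundle["rcbray"] = rc

    if "network" in stages:
        net = nw.build_network(cm, r_threshold=cfg.r_threshold,
                               p_threshold=cfg.p_threshold,
                               prevalence_min=cfg.prevalence_min)
        net.edges.to_csv(out / "network_edges.tsv", sep="\t",
                         float_format="%.6f", index=False)
        if net.graph.number_of_edges():
            import networkx as nx

            nx.write_graphml(net.graph, out / "network.graphml")
            props = nw.topology(net, seed=_child_seed(cfg.seed, 6))
            props.to_frame("value").to_csv(out / "network_properties.tsv",
                                           sep="\t", float_format="%.6f",
                                           index_label="property")
            _, summary = nw.er_ensemble(
                net.graph.number_of_nodes(), net.graph.number_of_edges(),
                n_rand=min(cfg.extra.get("n_rand", 1000), 1000),
                seed=_child_seed(cfg.seed, 7))
            summary.to_csv(out / "network_random_ensemble.tsv", sep="\t",
                           float_format="%.6f", index_label="metric")
            net.properties = props
            net.random_summary = summary
        bundle["network"] = net

    log = {
        "package": "lakemicro",
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items() if k != "extra"},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    logger.info("pipeline finished; outputs in %s", out)
    return bundle
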