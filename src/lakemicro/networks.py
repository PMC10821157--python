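"""Co-occurrence network construction, topology and random-graph nulls.

Edges are Spearman correlations between OTU abundance profiles that are
both strong (|rho| > 0.8) and significant after Benjamini–Hochberg
adjustment over all tested pairs (adjusted p < 0.01); both thresholds
are strict and tunable. Topological properties are compared against an
ensemble of Erdős–Rényi G(n, M) graphs with the same node and edge
counts.

Graphs are exposed as :class:`networkx.Graph` (easy to export/extend);
path and community metrics run through python-igraph's C backend so a
1000-replicate ensemble stays cheap.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CommunityMatrix

logger = logging.getLogger("lakemicro")

__all__ = [
    "NetworkResult",
    "build_network",
    "topology",
    "er_ensemble",
    "sample_subnetwork_properties",
]

TOPOLOGY_METRICS = (
    "nodes", "edges", "avg_degree", "density", "avg_clustering",
    "avg_path_length", "geodesic_efficiency", "harmonic_geodesic_distance",
    "modularity",
)


@dataclass
class NetworkResult:
    """Thresholded signed co-occurrence graph plus its edge table."""

    graph: nx.Graph
    edges: pd.DataFrame  # node1, node2, rho, p, adj_p, sign
    properties: pd.Series | None = None
    random_summary: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def build_network(
    cm: CommunityMatrix,
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
    prevalence_min: float = 1 / 3,
) -> NetworkResult:
    """Build the thresholded Spearman co-occurrence network.

    OTUs are prefiltered to those present in at least ``prevalence_min``
    of samples; all pairwise Spearman correlations over samples are then
    tested, p-values BH-adjusted over all tested pairs, and edges kept
    when |rho| > ``r_threshold`` and adjusted p < ``p_threshold``.
    Isolated nodes are dropped. An empty result is returned (with a
    warning) when no edge survives.
    """
    if cm.n_samples < 8:
        raise ValueError("need at least 8 samples for a meaningful Spearman p")
    prevalent = (cm.counts > 0).mean(axis=0) >= prevalence_min
    sub = cm.counts.loc[:, prevalent]
    otus = list(sub.columns)
    t = len(otus)
    if t < 2:
        raise ValueError("fewer than 2 OTUs pass the prevalence filter")
    rho, pval = stats.spearmanr(sub.to_numpy())
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(t, k=1)
    padj = multipletests(pval[iu], method="fdr_bh")[1]
    keep = (np.abs(rho[iu]) > r_threshold) & (padj < p_threshold)
    edges = pd.DataFrame(
        {
            "node1": [otus[i] for i in iu[0][keep]],
            "node2": [otus[j] for j in iu[1][keep]],
            "rho": rho[iu][keep],
            "p": pval[iu][keep],
            "adj_p": padj[keep],
        }
    )
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.node1, row.node2, rho=row.rho, adj_p=row.adj_p, sign=row.sign)
    if g.number_of_edges() == 0:
        logger.warning("no edges survive |rho| > %.2f and adjusted p < %.2g",
                       r_threshold, p_threshold)
    return NetworkResult(
        graph=g,
        edges=edges,
        params={"r_threshold": r_threshold, "p_threshold": p_threshold,
                "prevalence_min": prevalence_min, "n_tested": len(iu[0])},
    )


def _to_igraph(g: nx.Graph) -> ig.Graph:
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    return ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges], directed=False
    )


def topology(net, method: str = "greedy", seed: int = 0) -> pd.Series:
    """Topological property record of a network.

    Accepts a :class:`NetworkResult` or a bare graph. Average path
    length is computed on the largest connected component; geodesic
    efficiency averages 1/d over *all* node pairs (disconnected pairs
    contribute 0) and the harmonic geodesic distance is the harmonic
    mean of the finite geodesics. Modularity uses greedy (CNM)
    modularity maximization on the unsigned graph; ``method="louvain"``
    switches to multilevel optimization (seeded).
    """
    g = net.graph if isinstance(net, NetworkResult) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0 or e == 0:
        return pd.Series({k: np.nan for k in TOPOLOGY_METRICS})
    gi = _to_igraph(g)
    d = np.array(gi.distances())
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    finite = np.isfinite(dv)
    inv = np.where(finite, 1.0 / np.where(dv > 0, dv, np.inf), 0.0)
    if method == "greedy":
        clustering = gi.community_fastgreedy().as_clustering()
    elif method == "louvain":
        _random.seed(seed)
        clustering = gi.community_multilevel()
    else:
        raise ValueError("method must be 'greedy' or 'louvain'")
    rec = {
        "nodes": float(n),
        "edges": float(e),
        "avg_degree": 2.0 * e / n,
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else np.nan,
        "avg_clustering": gi.transitivity_avglocal_undirected(mode="zero"),
        "avg_path_length": float(dv[finite].mean()) if finite.any() else np.nan,
        "geodesic_efficiency": float(inv.mean()),
        "harmonic_geodesic_distance": (
            float(finite.sum() / inv[finite].sum()) if finite.any() else np.nan
        ),
        "modularity": float(gi.modularity(clustering)),
    }
    if isinstance(net, NetworkResult) and len(net.edges):
        pos = (net.edges["sign"] == "positive").mean() * 100
        rec["positive_pct"] = pos
        rec["negative_pct"] = 100.0 - pos
    return pd.Series(rec)


def er_ensemble(
    n_nodes: int,
    n_edges: int,
    n_rand: int = 1000,
    seed: int = 0,
    metrics=TOPOLOGY_METRICS,
    method: str = "greedy",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Topology of ``n_rand`` Erdős–Rényi G(n, M) random graphs.

    Returns ``(per_replicate, summary)`` where summary holds the mean
    and sd per metric. Every replicate has exactly ``n_edges`` edges, so
    average degree and density are identical across replicates.
    """
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("edge count infeasible for node count")
    _random.seed(seed)  # python-igraph draws from Python's random module
    rows = []
    for _ in range(n_rand):
        gi = ig.Graph.Erdos_Renyi(n=n_nodes, m=n_edges)
        rec = {}
        if "avg_degree" in metrics:
            rec["avg_degree"] = 2.0 * n_edges / n_nodes
        if "density" in metrics:
            rec["density"] = 2.0 * n_edges / (n_nodes * (n_nodes - 1))
        if "avg_clustering" in metrics:
            rec["avg_clustering"] = gi.transitivity_avglocal_undirected(mode="zero")
        if any(m in metrics for m in
               ("avg_path_length", "geodesic_efficiency", "harmonic_geodesic_distance")):
            d = np.array(gi.distances())
            dv = d[np.triu_indices(n_nodes, k=1)]
            finite = np.isfinite(dv)
            inv = np.where(finite, 1.0 / np.where(dv > 0, dv, np.inf), 0.0)
            if "avg_path_length" in metrics:
                rec["avg_path_length"] = float(dv[finite].mean())
            if "geodesic_efficiency" in metrics:
                rec["geodesic_efficiency"] = float(inv.mean())
            if "harmonic_geodesic_distance" in metrics:
                rec["harmonic_geodesic_distance"] = float(finite.sum() / inv[finite].sum())
        if "modularity" in metrics:
            if method == "louvain":
                cl = gi.community_multilevel()
            else:
                cl = gi.community_fastgreedy().as_clustering()
            rec["modularity"] = float(gi.modularity(cl))
        rows.append(rec)
    per = pd.DataFrame(rows)
    summary = pd.DataFrame({"mean": per.mean(), "sd": per.std(ddof=1)})
    return per, summary


def sample_subnetwork_properties(
    net: NetworkResult, cm: CommunityMatrix, method: str = "greedy", seed: int = 0
) -> pd.DataFrame:
    """Per-sample topology of the subgraph induced by the sample's taxa.

    For each sample, the pooled network is restricted to the OTUs with
    nonzero abundance in that sample and the topology record computed;
    samples inducing an empty (or single-node) subgraph yield NA rows.
    The table joins directly against an environment table for a
    property–environment correlation screen.
    """
    rows = {}
    for sid, counts in cm.counts.iterrows():
        present = set(counts.index[counts > 0]) & set(net.graph.nodes)
        sub = net.graph.subgraph(present)
        if sub.number_of_nodes() < 2 or sub.number_of_edges() == 0:
            rows[sid] = pd.Series({k: np.nan for k in TOPOLOGY_METRICS})
        else:
            rows[sid] = topology(sub, method=method, seed=seed)
    return pd.DataFrame.from_dict(rows, orient="index")
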