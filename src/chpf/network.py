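"""Critical-gene ranking in cell-status-specific gene regulatory networks.

Nodes of a directed TF->target network are scored by five centralities
(total degree, betweenness, closeness, eigenvector, PageRank), the five
per-metric ranks are integrated into a single Q statistic — the joint
order-statistic probability of the node's normalized rank ratios, smaller
meaning more central across the board — and the top 1% of the Q ranking
are called critical genes. Comparing the critical sets of the hypoxic and
normoxic networks nominates status-specific transcription factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CENTRALITY_COLUMNS = ["degree", "betweenness", "closeness", "eigenvector", "pagerank"]


@dataclass
class GeneNetwork:
    """Directed TF->target regulatory network."""

    edges: pd.DataFrame  # columns tf, target, optional weight
    tf_nodes: set = field(default_factory=set)
    isolates: list = field(default_factory=list)

    def __post_init__(self):
        if not {"tf", "target"} <= set(self.edges.columns):
            raise ValueError("edges require 'tf' and 'target' columns")
        self.edges = self.edges.astype({"tf": str, "target": str})
        self.tf_nodes = set(map(str, self.tf_nodes)) | set(self.edges["tf"])
        loops = self.edges["tf"] == self.edges["target"]
        if loops.any():
            logger.warning("dropping %d self-loop edges", int(loops.sum()))
            self.edges = self.edges[~loops].reset_index(drop=True)

    @property
    def nodes(self) -> list:
        seen = dict.fromkeys(self.edges["tf"])
        seen.update(dict.fromkeys(self.edges["target"]))
        seen.update(dict.fromkeys(map(str, self.isolates)))
        return list(seen)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges[["tf", "target"]].itertuples(index=False))
        return g


def compute_centralities(net: GeneNetwork) -> pd.DataFrame:
    """Five centrality metrics per node.

    Degree is total (in + out) degree on the directed graph; betweenness
    and closeness use the undirected view (harmonic closeness when the
    undirected view is disconnected); eigenvector centrality is computed
    on the undirected largest connected component (zero elsewhere);
    PageRank runs on the directed graph with damping 0.85.
    """
    g = net.to_networkx()
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    nodes = list(g.nodes)
    if g.number_of_edges() == 0:
        logger.warning("empty edge set: all centralities are zero")
        return pd.DataFrame(0.0, index=nodes, columns=CENTRALITY_COLUMNS)
    und = g.to_undirected()
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(und, normalized=True)
    if nx.is_connected(und):
        closeness = nx.closeness_centrality(und)
    else:
        n = len(nodes)
        closeness = {k: v / (n - 1) for k, v in nx.harmonic_centrality(und).items()}
    comp = max(nx.connected_components(und), key=len)
    if len(comp) <= 2:  # closed form; the dense eigensolver needs >= 3 nodes
        eig_cc = {n_: 1.0 / np.sqrt(len(comp)) for n_ in comp}
    else:
        eig_cc = nx.eigenvector_centrality_numpy(und.subgraph(comp))
    eigenvector = {n_: abs(eig_cc.get(n_, 0.0)) for n_ in nodes}
    pagerank = nx.pagerank(g, alpha=0.85)
    return pd.DataFrame(
        {
            "degree": [float(degree[n_]) for n_ in nodes],
            "betweenness": [betweenness[n_] for n_ in nodes],
            "closeness": [closeness[n_] for n_ in nodes],
            "eigenvector": [eigenvector[n_] for n_ in nodes],
            "pagerank": [pagerank[n_] for n_ in nodes],
        },
        index=nodes,
    )


def q_joint_probability(rank_ratios) -> float:
    """Joint order-statistic probability of normalized rank ratios.

    For sorted ratios r_(1) <= ... <= r_(n) in (0, 1], returns
    P(U_(1) <= r_(1), ..., U_(n) <= r_(n)) for uniform order statistics,
    via the classical recursion Q = n! V_n with
    V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_{(n-k+1)}^i / i!.
    Smaller Q means jointly more extreme (more central) ranks.
    """
    r = np.sort(np.asarray(rank_ratios, dtype=float))
    if np.any(~np.isfinite(r)) or np.any(r < 0) or np.any(r > 1):
        raise ValueError("rank ratios must lie in [0, 1]")
    n = r.size
    v = [1.0]
    for k in range(1, n + 1):
        acc = 0.0
        for i in range(1, k + 1):
            acc += (-1) ** (i - 1) * v[k - i] * r[n - k] ** i / math.factorial(i)
        v.append(acc)
    return float(max(math.factorial(n) * v[n], 0.0))


def q_statistic_aggregate(tbl: pd.DataFrame) -> pd.DataFrame:
    """Integrate the five centralities into a Q statistic per node.

    Each metric is converted to an average-tie rank (1 = most central)
    normalized by the node count; the Q statistic is the joint
    order-statistic probability over a node's five rank ratios, and
    ``q_rank`` is its ascending rank (1 = most critical).
    """
    missing = [c for c in CENTRALITY_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"missing centrality columns: {missing}")
    if tbl[CENTRALITY_COLUMNS].isna().any().any():
        raise ValueError("NaN centrality values")
    n = len(tbl)
    out = tbl.copy()
    ratios = np.empty((n, len(CENTRALITY_COLUMNS)))
    for j, col in enumerate(CENTRALITY_COLUMNS):
        ranks = stats.rankdata(-out[col].to_numpy(), method="average")
        out[f"rank_{col}"] = ranks
        ratios[:, j] = ranks / n
    out["q_value"] = [q_joint_probability(ratios[i]) for i in range(n)]
    out["q_rank"] = stats.rankdata(out["q_value"].to_numpy(), method="average")
    return out


@dataclass
class CriticalGeneSet:
    """Top-fraction critical genes of one network's Q ranking."""

    label: str
    genes: list
    tf_subset: list
    top_frac: float


def critical_genes(
    tbl: pd.DataFrame,
    top_frac: float = 0.01,
    tf_nodes=(),
    label: str = "",
) -> CriticalGeneSet:
    """Select the ceil(top_frac * N) genes with smallest Q (boundary ties included)."""
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must be in (0, 1]")
    if "q_value" not in tbl.columns:
        raise ValueError("run q_statistic_aggregate first")
    n = len(tbl)
    k = math.ceil(top_frac * n)
    qs = tbl["q_value"].to_numpy()
    threshold = np.sort(qs)[k - 1]
    sel = tbl.index[qs <= threshold]
    genes = sorted(sel, key=lambda g: (tbl.loc[g, "q_value"], str(g)))
    tf_nodes = set(map(str, tf_nodes))
    return CriticalGeneSet(
        label=label,
        genes=[str(g) for g in genes],
        tf_subset=[str(g) for g in genes if str(g) in tf_nodes],
        top_frac=top_frac,
    )


def status_specific_tfs(
    critical_h: CriticalGeneSet, critical_n: CriticalGeneSet
) -> list:
    """TFs critical in the hypoxic network but absent from the normoxic critical set."""
    if critical_h.top_frac != critical_n.top_frac:
        raise ValueError("critical sets must use the same top_frac")
    other = set(critical_n.genes)
    return [g for g in critical_h.tf_subset if g not in other]
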