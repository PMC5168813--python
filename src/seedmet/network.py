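"""Signed correlation networks, communities and the ms1/ms2 bipartition.

Pairwise Spearman correlations among metabolites (and germination traits)
are thresholded — FDR-adjusted p below q and |r| above r_min — into an
undirected signed graph.  The graph is split into communities by the
Walktrap random-walk algorithm (|r| as walk weights, cut at maximal
modularity), each community is 2-colored into an internally positive,
mutually negative pair of subsets by minimising signed-edge frustration, and
the subsets are assembled across communities into two global, mutually
anti-correlated metabolite sets.  The set whose members correlate negatively
with germination percent is labelled ms1; its antagonist is ms2.

Frustration of a 2-coloring counts (or |r|-weights) the edges that violate
structural balance: a positive edge across the two colors or a negative edge
within one color.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "NetworkAttributes",
    "MetaboliteSets",
    "spearman_matrix",
    "bh_fdr",
    "adjust_p_matrix",
    "build_network",
    "network_attributes",
    "threshold_scan",
    "walktrap_communities",
    "signed_bipartition",
    "frustration",
    "assemble_metabolite_sets",
    "germination_edge_report",
]

EXACT_BIPARTITION_MAX_NODES = 15


# ---------------------------------------------------------------------------
# correlations and significance


def spearman_matrix(
    columns: pd.DataFrame,
    min_n: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rank correlation with two-sided p-values.

    Ties receive average ranks; missing values are deleted pairwise (so
    germination traits undefined for some plots still correlate over the
    plots where they exist); p-values use the t approximation with the
    pairwise sample size.  Constant columns have undefined correlations and
    are dropped with a warning; pairs with fewer than ``min_n`` complete
    observations get an undefined (missing) correlation.
    """
    nunique = columns.nunique(dropna=True)
    constant = list(nunique.index[nunique <= 1])
    if constant:
        log.warning("excluded constant columns from correlation: %s", constant)
        columns = columns.drop(columns=constant)
    if columns.shape[1] < 2:
        raise ValueError("need at least two non-constant columns")
    r = columns.corr(method="spearman", min_periods=max(min_n, 3))
    present = columns.notna().to_numpy(dtype=float)
    n = present.T @ present
    rv = r.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isclose(np.abs(rv), 1.0), 0.0, p)
    p = np.where(np.isnan(rv), np.nan, p)
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    np.fill_diagonal(r.values, 1.0)
    np.fill_diagonal(p.values, 0.0)
    return r, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(len(p), np.nan)
    tested = ~np.isnan(p)  # untested pairs stay undefined
    pt = p[tested]
    m = len(pt)
    if m:
        order = np.argsort(pt, kind="mergesort")
        ranked = pt[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adjusted, 1.0)
        out[tested] = res
    return out


def adjust_p_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """BH adjustment over the upper triangle of a symmetric p-value matrix."""
    iu = np.triu_indices(len(p), k=1)
    flat = p.to_numpy()[iu]
    adj = bh_fdr(flat)
    out = np.zeros_like(p.to_numpy())
    out[iu] = adj
    out = out + out.T
    return pd.DataFrame(out, index=p.index, columns=p.columns)


# ---------------------------------------------------------------------------
# graph construction and attributes


def build_network(
    r: pd.DataFrame,
    p_adj: pd.DataFrame,
    r_min: float = 0.4,
    q: float = 0.05,
) -> nx.Graph:
    """Threshold correlations into an undirected signed graph.

    An edge (u, v) is retained when ``p_adj < q`` and ``|r| > r_min``; each
    edge carries ``r``, ``p_adj``, ``sign`` and ``weight = |r|`` attributes.
    Nodes without any retained edge are dropped.
    """
    g = nx.Graph()
    nodes = list(r.index)
    rv, pv = r.to_numpy(), p_adj.to_numpy()
    for i, j in zip(*np.triu_indices(len(nodes), k=1)):
        # float guard so that e.g. r_min = 1.0 still keeps perfect pairs
        if pv[i, j] < q and abs(rv[i, j]) > r_min - 1e-9:
            g.add_edge(nodes[i], nodes[j], r=float(rv[i, j]),
                       p_adj=float(pv[i, j]),
                       sign=1 if rv[i, j] > 0 else -1,
                       weight=abs(float(rv[i, j])))
    return g


@dataclass
class NetworkAttributes:
    """Graph-theory measures of a signed correlation network."""

    n_nodes: int
    n_pos_edges: int
    n_neg_edges: int
    n_edges: int
    edge_node_ratio: float
    avg_degree: float
    diameter: float
    density: float
    avg_path_length: float
    transitivity: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def network_attributes(net: nx.Graph) -> NetworkAttributes:
    """Compute the standard attribute panel on the unsigned topology.

    Diameter and average path length are taken over the largest connected
    component.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network has no attributes")
    e = net.number_of_edges()
    pos = sum(1 for *_, d in net.edges(data=True) if d.get("sign", 1) > 0)
    giant = net.subgraph(max(nx.connected_components(net), key=len))
    return NetworkAttributes(
        n_nodes=n,
        n_pos_edges=pos,
        n_neg_edges=e - pos,
        n_edges=e,
        edge_node_ratio=e / n,
        avg_degree=2.0 * e / n,
        diameter=float(nx.diameter(giant)) if giant.number_of_nodes() > 1 else 0.0,
        density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        avg_path_length=(
            float(nx.average_shortest_path_length(giant))
            if giant.number_of_nodes() > 1 else 0.0
        ),
        transitivity=float(nx.transitivity(net)),
    )


def threshold_scan(
    r: pd.DataFrame,
    p_adj: pd.DataFrame,
    thresholds,
    q: float = 0.05,
) -> pd.DataFrame:
    """Network attributes per candidate |r| cutoff (ascending thresholds)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for r_min in thresholds:
        net = build_network(r, p_adj, r_min=r_min, q=q)
        row = {"r_min": r_min}
        if net.number_of_nodes():
            row.update(network_attributes(net).to_dict())
        else:
            row.update({"n_nodes": 0, "n_edges": 0})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# communities


def walktrap_communities(net: nx.Graph, steps: int = 4) -> dict[str, int]:
    """Walktrap community detection with |r| edge weights.

    Random walks require non-negative weights, so the walk uses the
    correlation magnitude; the sign stays on the edge attribute.  The
    agglomerative dendrogram is cut at maximal modularity.  Deterministic
    for a fixed input graph.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges()]
    weights = [abs(d.get("weight", d.get("r", 1.0)))
               for *_, d in net.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges)
    dendrogram = g.community_walktrap(weights=weights or None, steps=steps)
    clustering = dendrogram.as_clustering()
    return {v: int(clustering.membership[index[v]]) for v in nodes}


# ---------------------------------------------------------------------------
# signed bipartition (structural balance)


def frustration(
    net: nx.Graph, side: dict, weighted: bool = True
) -> float:
    """Total weight of edges violating the 2-coloring ``side``.

    A positive edge is frustrated when its endpoints differ in color; a
    negative edge when they agree.
    """
    total = 0.0
    for u, v, d in net.edges(data=True):
        violated = (side[u] != side[v]) if d["sign"] > 0 else (side[u] == side[v])
        if violated:
            total += abs(d.get("r", 1.0)) if weighted else 1.0
    return total


def _signed_weight_matrix(net: nx.Graph, nodes: list, weighted: bool) -> np.ndarray:
    index = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v, d in net.edges(data=True):
        mag = abs(d.get("r", 1.0)) if weighted else 1.0
        w[index[u], index[v]] = w[index[v], index[u]] = d["sign"] * mag
    return w


def _matrix_frustration(w: np.ndarray, s: np.ndarray) -> float:
    # per edge: satisfied contributes 0, violated its |weight|
    return float((np.abs(w).sum() - s @ w @ s) / 4.0)


def _local_search_vec(w: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Steepest-descent single-node flips until no move reduces frustration."""
    ws = w @ s
    while True:
        gains = -s * ws  # frustrated-minus-satisfied incident weight
        i = int(np.argmax(gains))
        if gains[i] <= 1e-12:
            return s
        s[i] = -s[i]
        ws += w[:, i] * (2.0 * s[i])


def signed_bipartition(
    community_subgraph: nx.Graph,
    weighted: bool = True,
    method: str = "auto",
    n_restarts: int = 50,
    rng_seed: int = 0,
) -> tuple[frozenset, frozenset, float]:
    """Minimum-frustration 2-coloring of a signed (sub)graph.

    Positive edges prefer same-side endpoints, negative edges opposite
    sides; the objective is the (|r|-weighted by default) count of violated
    edges.  Exact exhaustive search is used for graphs of at most
    ``EXACT_BIPARTITION_MAX_NODES`` nodes; larger graphs use seeded
    multi-restart steepest-descent local search.  ``method`` forces
    "exact" or "heuristic".  Returns ``(side_a, side_b, frustration)`` with
    the side containing the lexicographically smallest node first.
    """
    nodes = sorted(community_subgraph.nodes())
    if not nodes:
        raise ValueError("community must have at least one node")
    if method not in ("auto", "exact", "heuristic"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = ("exact" if len(nodes) <= EXACT_BIPARTITION_MAX_NODES
                  else "heuristic")

    w = _signed_weight_matrix(community_subgraph, nodes, weighted)
    n = len(nodes)
    if method == "exact":
        best_s, best_f = None, np.inf
        # fix the first node's color: the objective is flip-symmetric
        for bits in itertools.product((-1.0, 1.0), repeat=n - 1):
            s = np.array((1.0,) + bits)
            f = _matrix_frustration(w, s)
            if f < best_f - 1e-12:
                best_s, best_f = s, f
        s = best_s
    else:
        rng = np.random.default_rng(rng_seed)
        best_s, best_f = None, np.inf
        for restart in range(n_restarts):
            if restart == 0:
                # balance-guided start: BFS propagating expected signs
                side = _sign_bfs_init(community_subgraph, nodes)
                s = np.array([1.0 if side[v] == 0 else -1.0 for v in nodes])
            else:
                s = rng.choice([-1.0, 1.0], size=n)
            s = _local_search_vec(w, s)
            f = _matrix_frustration(w, s)
            if f < best_f - 1e-12:
                best_s, best_f = s.copy(), f
        s = best_s

    a = frozenset(v for v, si in zip(nodes, s) if si == s[0])
    b = frozenset(v for v, si in zip(nodes, s) if si != s[0])
    return a, b, _matrix_frustration(w, s)


def _sign_bfs_init(net: nx.Graph, nodes: list) -> dict:
    """Initial coloring by propagating edge signs along a BFS forest."""
    side: dict = {}
    for root in nodes:
        if root in side:
            continue
        side[root] = 0
        queue = [root]
        while queue:
            v = queue.pop()
            for u in net[v]:
                if u not in side:
                    side[u] = side[v] if net[v][u]["sign"] > 0 else 1 - side[v]
                    queue.append(u)
    return side


# ---------------------------------------------------------------------------
# global metabolite sets


@dataclass
class MetaboliteSets:
    """Global ms1/ms2 assignment with its frustration."""

    assignment: dict[str, str]          # node -> "ms1" | "ms2" | "unassigned"
    frustrated_weight: float            # total |r| weight of violated edges
    frustrated_edges: int               # violated edge count (unweighted)
    subset_labels: dict[str, tuple[int, int]] = field(default_factory=dict)
    orientation_defined: bool = True

    def members(self, label: str) -> set[str]:
        return {v for v, s in self.assignment.items() if s == label}


def assemble_metabolite_sets(
    partition: dict[str, int],
    bipartitions: dict[int, tuple[frozenset, frozenset, float]],
    net: nx.Graph,
    germination_percent_node: str | None = None,
) -> MetaboliteSets:
    """Assemble per-community subsets into the two global metabolite sets.

    A meta-graph is built whose nodes are community subsets; a signed
    meta-edge between two subsets aggregates the inter-subset correlations
    (weight = sum of |r|, sign = the majority sign by weight).  The
    meta-graph is 2-colored by the same frustration minimisation, giving the
    global bipartition.  Orientation: the side holding the majority of
    metabolites negatively correlated with germination percent is ms1.  With
    no germination anchor (or no meta-edges) the labelling falls back to a
    deterministic but arbitrary orientation and ``orientation_defined`` is
    False.
    """
    # map node -> (community, subset index)
    subset_of: dict[str, tuple[int, int]] = {}
    for cid, (a, b, _) in bipartitions.items():
        for v in a:
            subset_of[v] = (cid, 0)
        for v in b:
            subset_of[v] = (cid, 1)

    meta = nx.Graph()
    meta.add_nodes_from(sorted(set(subset_of.values())))
    agg: dict[tuple, float] = {}
    for u, v, d in net.edges(data=True):
        if u not in subset_of or v not in subset_of:
            continue
        su, sv = subset_of[u], subset_of[v]
        if su == sv:
            continue
        key = (min(su, sv), max(su, sv))
        agg[key] = agg.get(key, 0.0) + d["sign"] * abs(d.get("r", 1.0))
    for (su, sv), signed_w in agg.items():
        if signed_w != 0.0:
            meta.add_edge(su, sv, r=abs(signed_w), weight=abs(signed_w),
                          sign=1 if signed_w > 0 else -1)

    if meta.number_of_edges() == 0:
        side = {s: 0 for s in meta.nodes()}
        orientation_possible = False
    else:
        a, b, _ = signed_bipartition(meta)
        side = {s: (0 if s in a else 1) for s in meta.nodes()}
        orientation_possible = True

    assignment = {
        v: ("ms1" if side[subset_of[v]] == 0 else "ms2")
        for v in subset_of
    }
    for v in net.nodes():
        assignment.setdefault(v, "unassigned")

    oriented = False
    if germination_percent_node is not None and germination_percent_node in net:
        neg_partners = [u for u in net[germination_percent_node]
                        if net[germination_percent_node][u]["sign"] < 0
                        and u in subset_of]
        if neg_partners:
            votes_ms1 = sum(assignment[u] == "ms1" for u in neg_partners)
            if votes_ms1 < len(neg_partners) - votes_ms1:
                for v in subset_of:
                    assignment[v] = "ms2" if assignment[v] == "ms1" else "ms1"
            oriented = True

    # score the final assignment on the metabolite subgraph
    scored = net.subgraph(subset_of.keys())
    side_final = {v: (0 if assignment[v] == "ms1" else 1) for v in scored.nodes()}
    return MetaboliteSets(
        assignment=assignment,
        frustrated_weight=frustration(scored, side_final, weighted=True),
        frustrated_edges=int(frustration(scored, side_final, weighted=False)),
        subset_labels=subset_of,
        orientation_defined=oriented and orientation_possible,
    )


def germination_edge_report(
    net: nx.Graph,
    sets: MetaboliteSets,
    trait_nodes: tuple[str, ...] = ("percent", "t50", "sd_plate"),
) -> pd.DataFrame:
    """Metabolite partners of each germination trait, with set consistency.

    The expected pattern: metabolites negatively correlated with germination
    percent (or positively with T50 / SD-plate) lie in ms1; the reverse in
    ms2.  The ``consistent`` column marks each edge; the overall consistency
    score is the mean of that column.
    """
    rows = []
    for trait in trait_nodes:
        if trait not in net:
            continue
        for u in sorted(net[trait]):
            if u in trait_nodes:
                continue
            d = net[trait][u]
            member = sets.assignment.get(u, "unassigned")
            if trait == "percent":
                expected = "ms1" if d["sign"] < 0 else "ms2"
            else:  # t50, sd_plate: slower / less uniform germination
                expected = "ms1" if d["sign"] > 0 else "ms2"
            rows.append({
                "trait": trait, "metabolite": u, "r": d["r"],
                "sign": d["sign"], "set": member, "expected_set": expected,
                "consistent": member == expected,
            })
    return pd.DataFrame(rows, columns=["trait", "metabolite", "r", "sign",
                                       "set", "expected_set", "consistent"])
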