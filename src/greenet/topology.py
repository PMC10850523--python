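"""Topology of the ecological network.

Sources become nodes, corridors become edges of a simple undirected graph,
and each node gets the nine standard indicators: degree, local clustering,
classic closeness (within its component), betweenness (normalized by
(n-1)(n-2)/2), eccentricity, eigenvector centrality (max-normalized),
PageRank (damping 0.85), community label from seeded modularity
maximization, plus the graph-level average path length (mean hops over
connected pairs) and modularity Q.  All indicators are computed on the
unweighted graph; corridor cost/G/tier ride along as edge attributes.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import SourceSet
from .gravity import TieredCorridor
from .rasters import ConfigError


def build_graph(
    sources: SourceSet, tiered_corridors: list[TieredCorridor]
) -> nx.Graph:
    """Simple undirected graph: one edge per connected source pair.

    Parallel corridors between a pair collapse to a single edge keeping the
    minimum cost.
    """
    g = nx.Graph()
    for p in sources.patches:
        g.add_node(
            p.id,
            x=p.centroid[0],
            y=p.centroid[1],
            area_m2=p.area_m2,
            dPC=sources.dPC.get(p.id, float("nan")),
            land_class=p.land_class,
        )
    known = set(g.nodes)
    for tc in tiered_corridors:
        c = tc.corridor
        if c.src_id not in known or c.dst_id not in known:
            raise ConfigError(
                f"corridor references unknown source ({c.src_id}, {c.dst_id})"
            )
        if c.src_id == c.dst_id:
            continue
        attrs = dict(cost=c.cost, length_m=c.length_m, G=tc.G, tier=tc.tier)
        if g.has_edge(c.src_id, c.dst_id):
            if c.cost < g.edges[c.src_id, c.dst_id]["cost"]:
                g.edges[c.src_id, c.dst_id].update(attrs)
        else:
            g.add_edge(c.src_id, c.dst_id, **attrs)
    return g


def eigenvector_max_normalized(g: nx.Graph) -> dict:
    """Eigenvector centrality by power iteration, scaled so the max is 1."""
    nodes = sorted(g.nodes)
    if not nodes:
        return {}
    a = nx.to_numpy_array(g, nodelist=nodes)
    if not a.any():
        return {v: 0.0 for v in nodes}
    x = np.ones(len(nodes))
    shifted = a + np.eye(len(nodes))  # shift avoids bipartite oscillation
    for _ in range(10_000):
        nxt = shifted @ x
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.abs(nxt - x).sum() < 1e-12:
            x = nxt
            break
        x = nxt
    x = np.abs(x)
    return dict(zip(nodes, x / x.max()))


def average_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length (hops) over connected node pairs."""
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for src, dists in nx.all_pairs_shortest_path_length(sub):
            for dst, d in dists.items():
                if src < dst:
                    total += d
                    pairs += 1
    return total / pairs if pairs else float("nan")


def detect_communities(g: nx.Graph, seed: int = 0):
    """Seeded Louvain modularity communities with canonical integer labels.

    Labels are assigned in ascending order of each community's smallest
    node id, so identical partitions always get identical labels.  Returns
    ``(labels, Q)``; an edgeless graph is all singletons with Q = 0.
    """
    if g.number_of_nodes() == 0:
        raise ConfigError("community detection needs a non-empty graph")
    if g.number_of_edges() == 0:
        return {v: i for i, v in enumerate(sorted(g.nodes))}, 0.0
    comms = nx.community.louvain_communities(g, weight=None, seed=seed)
    comms = sorted(comms, key=min)
    labels = {v: i for i, c in enumerate(comms) for v in c}
    q = nx.community.modularity(g, comms, weight=None)
    return labels, float(q)


def topology_indicators(g: nx.Graph, seed: int = 0) -> pd.DataFrame:
    """Per-node table of the nine indicators (plus graph-level columns).

    Isolated nodes get closeness and eccentricity 0 with ``isolated=True``.
    """
    nodes = sorted(g.nodes)
    degree = dict(g.degree)
    clustering = nx.clustering(g)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    n = g.number_of_nodes()
    betweenness = nx.betweenness_centrality(g, normalized=n > 2)
    eigen = eigenvector_max_normalized(g)
    pagerank = nx.pagerank(g, alpha=0.85, tol=1e-9, max_iter=1000) if n else {}
    ecc: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            ecc[next(iter(comp))] = 0
        else:
            ecc.update(nx.eccentricity(sub))
    labels, q = detect_communities(g, seed=seed)
    apl = average_path_length(g)
    df = pd.DataFrame(
        {
            "node": nodes,
            "degree": [degree[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "closeness": [closeness[v] if degree[v] else 0.0 for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "eccentricity": [ecc[v] for v in nodes],
            "eigenvector": [eigen[v] for v in nodes],
            "pagerank": [pagerank[v] for v in nodes],
            "community": [labels[v] for v in nodes],
            "isolated": [degree[v] == 0 for v in nodes],
        }
    ).set_index("node")
    df.attrs["average_path_length"] = apl
    df.attrs["modularity_Q"] = q
    return df


def clustering_vs_random_baseline(
    g: nx.Graph, seed: int = 0, n_rewires: int = 20
) -> dict:
    """Mean clustering of the graph vs seeded degree-preserving rewirings.

    A small-world style check: a ratio well above 1 indicates clustering in
    excess of the degree-matched random expectation.
    """
    obs = nx.average_clustering(g) if g.number_of_nodes() else float("nan")
    rng = np.random.default_rng(seed)
    baseline = []
    m = g.number_of_edges()
    for _ in range(n_rewires):
        h = g.copy()
        if m > 1:
            try:
                nx.double_edge_swap(
                    h, nswap=4 * m, max_tries=40 * m + 100,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXError:
                pass
        baseline.append(nx.average_clustering(h))
    base = float(np.mean(baseline)) if baseline else float("nan")
    return {
        "observed": obs,
        "rewired_mean": base,
        "ratio": obs / base if base else float("inf"),
    }


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def brute_force_pairs(g: nx.Graph):
    """All unordered node pairs (test/oracle helper)."""
    return itertools.combinations(sorted(g.nodes), 2)
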