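"""Network optimization (stepping stones + corridors) and attack robustness.

Optimization adds, for each weak carbon node, edges to its nearest
non-adjacent nodes (by corridor cost, falling back to straight-line
distance) and inserts stepping-stone nodes at the geometric midpoints of
long incident corridors.  The effect is verified with attack simulations:
nodes are removed in a seeded random order or maliciously by descending
initial degree (ties broken by ascending node id), a pluggable recovery
rule may restore them, and three statistics track the damage:

    D = 1 - (N_r - N_d) / N      node recovery robustness
    E = 1 - (M_r - M_e) / M      edge recovery robustness
    R = C / (N - N_r)            connectivity robustness

with N/M the original node/edge counts, N_r/M_r the cumulative removals,
N_d/M_e the recoveries and C the giant-component size.  Recovery can
transiently push D, E or R above 1; values are clamped to [0, 1] and the
clamp is counted in the curve's ``clamped`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .rasters import ConfigError


# ---------------------------------------------------------------------------
# optimization

@dataclass
class OptimizationPlan:
    new_edges: list[tuple[int, int]] = field(default_factory=list)
    new_stepping_stones: list[dict] = field(default_factory=list)
    rationale: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.new_edges) + len(self.new_stepping_stones)


def _pair_cost(g: nx.Graph, u: int, v: int, corridor_costs: dict) -> float:
    key = (min(u, v), max(u, v))
    if key in corridor_costs:
        return corridor_costs[key]
    try:
        return math.hypot(
            g.nodes[u]["x"] - g.nodes[v]["x"], g.nodes[u]["y"] - g.nodes[v]["y"]
        )
    except KeyError:
        return 1.0


def propose_plan(
    g: nx.Graph,
    weak_nodes: list[int],
    corridors=None,
    k: int = 2,
    stone_length_threshold: float | None = None,
) -> OptimizationPlan:
    """Plan new corridors and stepping stones around the weak nodes.

    For each weak node: edges to its ``k`` nearest non-adjacent nodes (by
    corridor cost when a corridor exists, straight-line distance
    otherwise), plus a stepping stone at the midpoint of every incident
    corridor longer than ``stone_length_threshold`` metres (``None``
    disables stones).
    """
    if not weak_nodes:
        raise ConfigError("weak-node list must be non-empty")
    corridor_costs = {}
    corridor_by_pair = {}
    for c in corridors or []:
        key = (min(c.src_id, c.dst_id), max(c.src_id, c.dst_id))
        corridor_costs[key] = c.cost
        corridor_by_pair[key] = c
    plan = OptimizationPlan()
    seen = set()
    for w in weak_nodes:
        if w not in g:
            continue
        candidates = [
            v for v in g.nodes
            if v != w and not g.has_edge(w, v)
            and (min(w, v), max(w, v)) not in seen
        ]
        candidates.sort(key=lambda v: (_pair_cost(g, w, v, corridor_costs), v))
        for v in candidates[:k]:
            key = (min(w, v), max(w, v))
            seen.add(key)
            plan.new_edges.append(key)
            plan.rationale[key] = "corridor between adjacent nodes"
        if stone_length_threshold is not None:
            for u, v in g.edges(w):
                key = (min(u, v), max(u, v))
                corr = corridor_by_pair.get(key)
                if corr is None or corr.length_m <= stone_length_threshold:
                    continue
                mid = corr.path[len(corr.path) // 2]
                stone = {"on_edge": key, "cell": tuple(mid)}
                if stone not in plan.new_stepping_stones:
                    plan.new_stepping_stones.append(stone)
                    plan.rationale[("stone", key)] = (
                        "stepping stone at corridor midpoint"
                    )
    return plan


def apply_plan(g: nx.Graph, plan: OptimizationPlan) -> nx.Graph:
    """Return the optimized graph: stones split their corridor, edges added.

    Stepping stones become new nodes of degree 2 replacing edge (u, v) with
    (u, s) and (s, v); planned edges are then added.
    """
    h = g.copy()
    next_id = (max(h.nodes) + 1) if h.nodes else 1
    for stone in plan.new_stepping_stones:
        u, v = stone["on_edge"]
        if not h.has_edge(u, v):
            continue
        attrs = dict(h.edges[u, v])
        h.remove_edge(u, v)
        s = next_id
        next_id += 1
        h.add_node(s, stepping_stone=True)
        half = {**attrs}
        for key in ("cost", "length_m"):
            if key in half:
                half[key] = half[key] / 2.0
        h.add_edge(u, s, **half)
        h.add_edge(s, v, **half)
    for u, v in plan.new_edges:
        if not h.has_edge(u, v):
            h.add_edge(u, v, tier="added")
    return h


# ---------------------------------------------------------------------------
# attack schedules and robustness curves

@dataclass
class AttackSchedule:
    mode: str
    seed: int
    removals: list[int]


def make_schedule(
    g: nx.Graph, mode: str, seed: int = 0, fraction: float = 1.0
) -> AttackSchedule:
    """Removal order over ceil(fraction x N) nodes.

    ``random`` is a seeded uniform permutation; ``malicious`` removes by
    descending initial degree, ties by ascending node id.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must lie in (0, 1]")
    nodes = sorted(g.nodes)
    n_remove = math.ceil(fraction * len(nodes))
    if mode == "random":
        rng = np.random.default_rng(seed)
        order = [nodes[i] for i in rng.permutation(len(nodes))]
    elif mode == "malicious":
        order = sorted(nodes, key=lambda v: (-g.degree(v), v))
    else:
        raise ConfigError(f"unknown attack mode {mode!r}")
    return AttackSchedule(mode=mode, seed=seed, removals=order[:n_remove])


# recovery rules: callables (graph_now, node, original_neighbors) -> bool

def never_recover(h, node, neighbors) -> bool:
    return False


def always_recover(h, node, neighbors) -> bool:
    return True


def giant_component_recover(h, node, neighbors) -> bool:
    """Recover iff an original neighbor currently sits in the giant component."""
    if h.number_of_nodes() == 0:
        return False
    giant = max(nx.connected_components(h), key=lambda c: (len(c), -min(c)))
    return any(v in giant for v in neighbors if v in h)


RECOVERY_RULES = {
    "never": never_recover,
    "always": always_recover,
    "giant_component": giant_component_recover,
}


def robustness_curves(
    g: nx.Graph,
    schedule: AttackSchedule,
    recovery_rule="giant_component",
) -> pd.DataFrame:
    """D/E/R after each removal step of the schedule.

    Each step removes the next scheduled node and immediately offers it to
    the recovery rule; a recovered node rejoins with edges to the original
    neighbors currently in the giant component (all surviving original
    neighbors under the ``always`` rule).  A node is attacked at most once
    and recovery is attempted once, at its own removal step.  The sequence
    stops before N_r = N would make R undefined.
    """
    if isinstance(recovery_rule, str):
        recovery_rule = RECOVERY_RULES[recovery_rule]
    N = g.number_of_nodes()
    M = g.number_of_edges()
    if N == 0:
        raise ConfigError("empty graph")
    original_neighbors = {v: set(g.neighbors(v)) for v in g.nodes}
    h = g.copy()
    rows = []
    n_r = n_d = m_r = m_e = 0
    c0 = max((len(c) for c in nx.connected_components(h)), default=0)
    rows.append(
        _curve_row(0, N, M, n_r, n_d, m_r, m_e, c0)
    )
    for step, v in enumerate(schedule.removals, start=1):
        if v not in h:
            continue
        removed_edges = h.degree(v)
        h.remove_node(v)
        n_r += 1
        m_r += removed_edges
        if n_r >= N:
            break  # R undefined at total removal; truncate
        if recovery_rule(h, v, original_neighbors[v]):
            giant = (
                max(nx.connected_components(h), key=lambda c: (len(c), -min(c)))
                if h.number_of_nodes()
                else set()
            )
            if recovery_rule is always_recover:
                targets = [u for u in original_neighbors[v] if u in h]
            else:
                targets = [u for u in original_neighbors[v] if u in giant]
            h.add_node(v)
            for u in targets:
                h.add_edge(v, u)
            n_d += 1
            m_e += len(targets)
        c = max((len(c) for c in nx.connected_components(h)), default=0)
        rows.append(_curve_row(step, N, M, n_r, n_d, m_r, m_e, c))
    return pd.DataFrame(rows)


def _curve_row(step, N, M, n_r, n_d, m_r, m_e, c) -> dict:
    d_raw = 1.0 - (n_r - n_d) / N
    e_raw = 1.0 - (m_r - m_e) / M if M else 1.0
    r_raw = c / (N - n_r) if N > n_r else float("nan")
    clamp = lambda x: min(max(x, 0.0), 1.0)
    return {
        "step": step, "N": N, "M": M, "N_r": n_r, "N_d": n_d,
        "M_r": m_r, "M_e": m_e, "C": c,
        "D": clamp(d_raw), "E": clamp(e_raw), "R": clamp(r_raw),
        "clamped": any(not 0 <= x <= 1 for x in (d_raw, e_raw, r_raw)),
    }


def curve_auc(curve: pd.DataFrame, column: str = "R") -> float:
    """Mean of the statistic over the removal steps (normalized AUC)."""
    return float(curve[column].mean())


def compare_before_after(
    curves_pre: pd.DataFrame, curves_post: pd.DataFrame
) -> dict:
    """Stepwise deltas and summary of a before/after robustness comparison.

    Both curves must come from the same schedule; they are aligned on the
    step index (inner join), so added stepping-stone nodes — which are
    never attacked — do not break the comparison.
    """
    joined = curves_pre.merge(
        curves_post, on="step", suffixes=("_pre", "_post")
    )
    if joined.empty:
        raise ConfigError("curves share no steps; were schedules identical?")
    out = {"steps": len(joined)}
    for col in ("D", "E", "R"):
        delta = joined[f"{col}_post"] - joined[f"{col}_pre"]
        out[f"delta_{col}"] = delta.to_numpy()
        out[f"frac_improved_{col}"] = float((delta >= 0).mean())
        out[f"auc_diff_{col}"] = float(delta.mean())
    return out
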