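"""Pearson screening of indicator–carbon relationships and weak-node ranking.

Correlations carry the conventional significance stars on two-sided
p-values from the t-transform of the sample correlation:

    ``*``   0.01 <= p < 0.05
    ``**``  0.001 <= p < 0.01
    ``***`` p < 0.001

Weak carbon-sink nodes are those whose buffer-carbon means decrease
strictly with distance for BOTH the node and its source (a carbon-rich
core leaking into poorer surroundings), ranked by the absolute node–source
carbon difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import ConfigError

logger = logging.getLogger(__name__)

TOPOLOGY_COLUMNS = (
    "degree", "clustering", "closeness", "betweenness", "eccentricity",
    "eigenvector", "pagerank", "community",
)
METRIC_COLUMNS = (
    "CA", "LPI", "LSI", "COHESION", "DIVISION", "SPLIT", "CONTAG",
    "SHDI", "SHEI", "dPC",
)


def stars_for_p(p: float) -> str:
    """Half-open star intervals: p = 0.01 earns '*', p = 0.001 earns '**'."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_with_stars(x, y) -> tuple[float, float, str]:
    """Sample Pearson r, two-sided t-test p-value, and significance stars."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), stars_for_p(float(p))


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample sizes


def correlation_matrix(
    left: pd.DataFrame, right: pd.DataFrame
) -> CorrelationMatrix:
    """Pearson r/p/stars for every (left column, right column) pair.

    Rows with missing values are dropped pairwise; cells with fewer than 3
    complete pairs or a constant vector are flagged NA.
    """
    rows, cols = list(left.columns), list(right.columns)
    r = pd.DataFrame(np.nan, index=rows, columns=cols)
    p = pd.DataFrame(np.nan, index=rows, columns=cols)
    s = pd.DataFrame("", index=rows, columns=cols)
    n = pd.DataFrame(0, index=rows, columns=cols)
    for a in rows:
        for b in cols:
            pair = pd.concat([left[a], right[b]], axis=1).dropna()
            n.loc[a, b] = len(pair)
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r_, p_, s_ = pearson_with_stars(x, y)
            r.loc[a, b], p.loc[a, b], s.loc[a, b] = r_, p_, s_
    return CorrelationMatrix(r=r, p=p, stars=s, n=n)


def correlation_tables(
    topology: pd.DataFrame,
    metrics: pd.DataFrame,
    carbon: pd.DataFrame,
) -> dict[str, CorrelationMatrix]:
    """The three screening matrices: topology x carbon, landscape x carbon,
    topology x landscape.  Tables are joined on the node id."""
    carbon_cols = ["node_carbon"] + [
        c for c in carbon.columns if c.startswith("node_mean_")
    ]
    topo = topology.reset_index() if topology.index.name == "node" else topology
    joined = (
        topo.merge(metrics, on="node", suffixes=("", "_m"))
        .merge(carbon[["node"] + carbon_cols], on="node")
        .set_index("node")
    )
    if len(joined) < 3:
        raise ConfigError("need >= 3 complete rows for correlation screening")
    t_cols = [c for c in TOPOLOGY_COLUMNS if c in joined.columns]
    m_cols = [c for c in METRIC_COLUMNS if c in joined.columns]
    return {
        "topology_vs_carbon": correlation_matrix(joined[t_cols], joined[carbon_cols]),
        "landscape_vs_carbon": correlation_matrix(joined[m_cols], joined[carbon_cols]),
        "topology_vs_landscape": correlation_matrix(joined[t_cols], joined[m_cols]),
    }


def screen_weak_nodes(
    node_source_table: pd.DataFrame, strict: bool = True
) -> pd.DataFrame:
    """Rank weak carbon-sink nodes.

    Keeps nodes whose node AND source buffer profiles decrease with
    distance (strictly by default; ``strict=False`` accepts non-increasing
    node-mean sequences), sorted descending by |node - source| carbon.
    The result is invariant to the input row order.
    """
    df = node_source_table
    if strict:
        keep = df["node_monotone"] & df["source_monotone"]
    else:
        node_cols = sorted(
            (c for c in df.columns if c.startswith("node_mean_")),
            key=lambda c: int(c.split("_")[2][:-1]),
        )
        src_cols = [c.replace("node_", "source_", 1) for c in node_cols]
        nm = df[node_cols].to_numpy()
        sm = df[src_cols].to_numpy()
        keep = pd.Series(
            np.all(np.diff(nm, axis=1) <= 0, axis=1)
            & np.all(np.diff(sm, axis=1) <= 0, axis=1),
            index=df.index,
        )
    out = (
        df[keep]
        .sort_values(["carbon_difference", "node"], ascending=[False, True])
        .reset_index(drop=True)
    )
    if out.empty:
        logger.info("no nodes pass the weak-carbon screening")
    return out
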