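"""Gravity-model interaction strength between sources and corridor tiering.

The interaction between two sources is G = M_i M_j / d^r with standardized
node masses M, straight-line inter-source distance d, and exponent r.  The
default exponent is pair-specific: r_ij = d_ij / l_ij, the ratio of the
straight-line distance to the corridor (least-cost path) length, clamped to
[0.5, 3]; since the corridor can never be shorter than the straight line,
r_ij <= 1 in practice and the clamp only guards degenerate geometry.  A
constant exponent (r = 1) is available via ``r="constant"``.

Corridors are tiered primary/secondary/tertiary by G quantiles; ties at a
threshold go to the higher tier, so a network with all-equal G is all
primary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import ConfigError
from .resistance import Corridor

EPSILON_MASS = 0.01  # floor keeping standardized masses strictly positive

TIERS = ("primary", "secondary", "tertiary")


def node_mass(attributes: pd.DataFrame, columns=("area_m2", "dPC")) -> pd.Series:
    """Equal-weight min–max standardized mass per source.

    Each selected attribute is scaled to [0, 1]; the mass is their mean plus
    a small epsilon so no source has zero interaction.  A constant column
    contributes 0.5 for every source (all equal).
    """
    cols = [c for c in columns if c in attributes.columns]
    if not cols:
        raise ConfigError(f"none of {columns} present in the attribute table")
    scaled = []
    for c in cols:
        v = attributes[c].to_numpy(dtype=float)
        span = v.max() - v.min()
        scaled.append((v - v.min()) / span if span > 0 else np.full(len(v), 0.5))
    mass = np.mean(scaled, axis=0) + EPSILON_MASS
    return pd.Series(mass, index=attributes.index, name="mass")


def gravity(Mi: float, Mj: float, d: float, r: float = 1.0) -> float:
    """G = M_i M_j / d^r; undefined for coincident sources (d = 0)."""
    if d <= 0:
        raise ConfigError("gravity undefined for d <= 0 (degenerate pair)")
    return (Mi * Mj) / d**r


def pairwise_gravity(
    masses: dict[int, float],
    straight_d: dict[tuple[int, int], float],
    corridor_l: dict[tuple[int, int], float] | None = None,
    r: str | float = "auto",
    r_clamp: tuple[float, float] = (0.5, 3.0),
) -> dict[tuple[int, int], float]:
    """Gravity for every source pair with a known straight-line distance.

    ``r="auto"`` uses the pair-specific exponent d/l (clamped); a number
    uses that constant exponent for every pair.
    """
    out = {}
    for (i, j), d in straight_d.items():
        if r == "auto":
            length = (corridor_l or {}).get((i, j), d)
            exponent = d / length if length > 0 else 1.0
            exponent = min(max(exponent, r_clamp[0]), r_clamp[1])
        else:
            exponent = float(r)
        out[(i, j)] = gravity(masses[i], masses[j], d, exponent)
    return out


@dataclass
class TieredCorridor:
    corridor: Corridor
    G: float
    tier: str


def tier_corridors(
    corridors: list[Corridor],
    G: dict[tuple[int, int], float],
    q1: float = 2.0 / 3.0,
    q2: float = 1.0 / 3.0,
) -> list[TieredCorridor]:
    """Split corridors into primary/secondary/tertiary by G quantiles.

    G >= quantile(q1) -> primary; >= quantile(q2) -> secondary; else
    tertiary.  Tiering depends only on the ranks of G.
    """
    if not 0 < q2 < q1 < 1:
        raise ConfigError("need 0 < q2 < q1 < 1")
    if not corridors:
        return []
    values = np.array([G[(c.src_id, c.dst_id)] for c in corridors])
    t1, t2 = np.quantile(values, q1), np.quantile(values, q2)
    out = []
    for c, g in zip(corridors, values):
        tier = "primary" if g >= t1 else "secondary" if g >= t2 else "tertiary"
        out.append(TieredCorridor(corridor=c, G=float(g), tier=tier))
    return out


def gravity_table(G: dict[tuple[int, int], float]) -> pd.DataFrame:
    rows = [{"src": i, "dst": j, "G": g} for (i, j), g in sorted(G.items())]
    return pd.DataFrame(rows)
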