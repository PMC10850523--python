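"""Resistance surface construction and minimum-cumulative-resistance corridors.

Movement cost across the landscape is modelled by grading each of eight
ecological resistance factors into natural-breaks classes (1 = permeable,
n = hostile), combining the grades as a weighted sum, and accumulating
least-cost distance over the resulting surface on an 8-connected lattice:
a step between neighbouring cells costs the mean of the two cell
resistances times the step length (cell size, times sqrt(2) diagonally).
Corridors are the cost-minimal paths between every pair of source patches,
backtracked from the accumulated-cost computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .connectivity import SourceSet
from .rasters import AlignmentError, ConfigError, FactorRaster

logger = logging.getLogger(__name__)

#: factors where a *high* raw value means *low* resistance
DEFAULT_INVERTED = {"ndvi": True, "mndwi": True, "water_density": True,
                    "dem": False, "slope": False, "lucc": False,
                    "pop_density": False, "road_density": False}

DEFAULT_WEIGHTS = {name: 1.0 / 8.0 for name in DEFAULT_INVERTED}


@dataclass
class ResistanceSurface:
    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    grades_per_factor: int = 5
    weights: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values[np.isfinite(self.values)] <= 0):
            raise ConfigError("resistance values must be strictly positive")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Corridor:
    src_id: int
    dst_id: int
    path: list[tuple[int, int]]
    length_m: float
    cost: float

    def key(self) -> tuple:
        """Canonical geometric key for deduplication (orientation-free)."""
        cells = tuple(self.path)
        return min(cells, cells[::-1])


# ---------------------------------------------------------------------------
# natural breaks

def jenks_breaks(values: np.ndarray, n_classes: int, max_n: int = 1500):
    """Exact 1-D least-SSD contiguous partition (Fisher/Jenks natural breaks).

    Returns the n_classes - 1 interior break values (upper bounds of the
    lower classes).  For samples above ``max_n`` the breaks are computed on
    evenly spaced order statistics, which is deterministic and accurate for
    smooth value distributions.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    x = x[np.isfinite(x)]
    if n_classes < 2:
        raise ConfigError("n_classes must be >= 2")
    if len(np.unique(x)) < n_classes:
        raise ConfigError("fewer distinct values than classes")
    if len(x) > max_n:
        idx = np.linspace(0, len(x) - 1, max_n).round().astype(int)
        x = x[idx]
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i, j):  # SSD of x[i:j] for vector i, scalar j
        cnt = j - i
        return s2[j] - s2[i] - (s1[j] - s1[i]) ** 2 / cnt

    best = np.full((n_classes, n + 1), np.inf)
    argmin = np.zeros((n_classes, n + 1), dtype=int)
    ends = np.arange(1, n + 1)
    best[0, 1:] = seg_cost(np.zeros(n, dtype=int), ends)
    for k in range(1, n_classes):
        for j in range(k + 1, n + 1):
            i = np.arange(k, j)
            tot = best[k - 1, i] + seg_cost(i, j)
            m = int(np.argmin(tot))
            best[k, j] = tot[m]
            argmin[k, j] = i[m]
    cuts = []
    j = n
    for k in range(n_classes - 1, 0, -1):
        i = argmin[k, j]
        cuts.append(i)
        j = i
    cuts = cuts[::-1]
    return [float(x[c - 1]) for c in cuts]  # upper bound of each lower class


def jenks_grade(
    factor: FactorRaster, n_classes: int = 5, inverted: bool = False
) -> np.ndarray:
    """Grade a factor raster 1..n_classes by natural breaks.

    ``inverted=True`` maps high raw values to low grades (e.g. NDVI: dense
    vegetation resists movement least).
    """
    breaks = jenks_breaks(factor.values, n_classes)
    grades = np.searchsorted(np.asarray(breaks), factor.values, side="left") + 1
    grades = grades.astype(np.int32)
    if inverted:
        grades = n_classes + 1 - grades
    return grades


def build_resistance(
    graded: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
    *,
    cell_size: float,
    origin=(0.0, 0.0),
    grades_per_factor: int = 5,
) -> ResistanceSurface:
    """Cellwise weighted sum of graded factors (weights >= 0, sum to 1)."""
    weights = dict(weights or DEFAULT_WEIGHTS)
    if set(weights) != set(graded):
        raise ConfigError("weights must cover exactly the graded factors")
    w = np.array([weights[k] for k in graded])
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError("weights must be non-negative and sum to 1")
    shapes = {g.shape for g in graded.values()}
    if len(shapes) != 1:
        raise AlignmentError(f"graded rasters have mismatched shapes: {shapes}")
    values = sum(weights[k] * np.asarray(graded[k], dtype=float)
                 for k in graded)
    return ResistanceSurface(
        values=values,
        cell_size=cell_size,
        origin=origin,
        grades_per_factor=grades_per_factor,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# accumulated cost and corridors

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def lattice_graph(surface: ResistanceSurface) -> sparse.csr_matrix:
    """8-neighbour lattice with step cost mean(r_a, r_b) * step length."""
    r = surface.values
    rows, cols = r.shape
    idx = np.arange(rows * cols).reshape(rows, cols)

    def shifted(d):  # (source slice, destination slice) along one axis
        if d >= 0:
            return slice(0, -d if d else None), slice(d, None)
        return slice(-d, None), slice(0, d)

    data, src, dst = [], [], []
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:  # each pair stored once
        length = surface.cell_size * (math.sqrt(2) if dr and dc else 1.0)
        (sr0, sr1), (sc0, sc1) = shifted(dr), shifted(dc)
        cost = 0.5 * (r[sr0, sc0] + r[sr1, sc1]) * length
        ok = np.isfinite(cost)
        data.append(cost[ok].ravel())
        src.append(idx[sr0, sc0][ok].ravel())
        dst.append(idx[sr1, sc1][ok].ravel())
    n = rows * cols
    return sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(src), np.concatenate(dst))),
        shape=(n, n),
    )


def cost_distance(
    surface: ResistanceSurface, source_cells: np.ndarray
) -> np.ndarray:
    """Minimum accumulated cost from the nearest source cell to every cell.

    Source cells cost 0; unreachable cells are +inf.
    """
    source_cells = np.asarray(source_cells)
    if source_cells.size == 0:
        raise ConfigError("source_cells must be non-empty")
    rows, cols = surface.shape
    graph = lattice_graph(surface)
    flat = source_cells[:, 0] * cols + source_cells[:, 1]
    dist = dijkstra(graph, directed=False, indices=flat, min_only=True)
    return dist.reshape(rows, cols)


def least_cost_corridors(
    surface: ResistanceSurface,
    sources: SourceSet,
    drop_mediated: bool = False,
) -> list[Corridor]:
    """Minimum-cost path between the boundaries of every source pair.

    With ``drop_mediated=True`` a pair's corridor is discarded when its path
    crosses a third source patch: that connection is mediated by the
    intermediate source and is already represented by the two shorter
    corridors, so the network keeps only direct links (the convention that
    produces realistically sparse corridor systems).
    """
    patches = sources.patches
    if len(patches) < 2:
        raise ConfigError("need at least 2 sources for corridors")
    rows, cols = surface.shape
    graph = lattice_graph(surface)
    flats = [p.pixel_set[:, 0] * cols + p.pixel_set[:, 1] for p in patches]
    cell_owner = {}
    for p in patches:
        for row, col in p.pixel_set:
            cell_owner[(int(row), int(col))] = p.id
    corridors: dict[tuple, Corridor] = {}
    for i in range(len(patches) - 1):
        dist, pred, _ = dijkstra(
            graph,
            directed=False,
            indices=flats[i],
            min_only=True,
            return_predecessors=True,
        )
        for j in range(i + 1, len(patches)):
            cells_j = flats[j]
            costs_j = dist[cells_j]
            k = int(np.argmin(costs_j))
            if not np.isfinite(costs_j[k]):
                logger.warning(
                    "sources %d and %d are disconnected; corridor skipped",
                    patches[i].id, patches[j].id,
                )
                continue
            path_flat = _backtrack(pred, int(cells_j[k]))
            path = [(f // cols, f % cols) for f in path_flat]
            if drop_mediated and any(
                cell_owner.get(c, patches[i].id)
                not in (patches[i].id, patches[j].id)
                for c in path
            ):
                continue
            length = sum(
                surface.cell_size * math.hypot(a[0] - b[0], a[1] - b[1])
                for a, b in zip(path, path[1:])
            )
            corr = Corridor(
                src_id=patches[i].id,
                dst_id=patches[j].id,
                path=path,
                length_m=length,
                cost=float(costs_j[k]),
            )
            key = corr.key()
            if key not in corridors or corr.cost < corridors[key].cost:
                corridors[key] = corr
    return sorted(corridors.values(), key=lambda c: (c.src_id, c.dst_id))


def _backtrack(pred: np.ndarray, end: int) -> list[int]:
    path = [end]
    while pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def path_cost(surface: ResistanceSurface, path) -> float:
    """Recompute a path's accumulated cost from the surface (audit helper)."""
    r = surface.values
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        step = surface.cell_size * math.hypot(r1 - r0, c1 - c0)
        total += 0.5 * (r[r0, c0] + r[r1, c1]) * step
    return total
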