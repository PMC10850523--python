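"""FRAGSTATS-style landscape pattern indices per analysis window.

Implements the ten indices the pipeline correlates with carbon: CA, LPI,
LSI, COHESION, DIVISION, SPLIT (class-level structure of the class of
interest) and CONTAG, SHDI, SHEI (landscape-level diversity/aggregation),
with dPC joined from the connectivity stage.  Geometry uses the cell-edge
convention: patch perimeters count cell edges against anything that is not
the patch, window boundary included, so a single square patch has LSI
exactly 1.  Patches inside windows are 8-connected.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .connectivity import SourceSet
from .mspa import _STRUCT
from .rasters import LandUseRaster


def _patch_areas_perimeters(mask: np.ndarray, valid: np.ndarray):
    """Areas (cells) and perimeters (cell edges) of 8-connected patches."""
    labels, n = ndimage.label(mask & valid, structure=_STRUCT[8])
    areas, perims = [], []
    padded = np.pad(labels, 1)
    for pid in range(1, n + 1):
        cells = padded == pid
        area = int(cells.sum())
        perim = 0
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            perim += int((cells & ~np.roll(cells, shift, axis=ax)).sum())
        areas.append(area)
        perims.append(perim)
    return np.array(areas, float), np.array(perims, float)


def patch_structure_metrics(
    window: np.ndarray,
    class_of_interest: int,
    valid: np.ndarray | None = None,
    cell_area_ha: float = 1.0,
) -> dict:
    """CA, LPI, LSI, COHESION, DIVISION, SPLIT for one class in a window.

    ``valid`` masks the analysis window (cells outside it count as edge,
    like the window boundary).  CA is reported in hectares via
    ``cell_area_ha``; the ratio metrics are unit-free.
    """
    window = np.asarray(window)
    valid = np.ones(window.shape, bool) if valid is None else valid
    A = int(valid.sum())
    if A == 0:
        raise ValueError("empty analysis window")
    areas, perims = _patch_areas_perimeters(window == class_of_interest, valid)
    if len(areas) == 0:
        return {
            "CA": 0.0, "LPI": 0.0, "LSI": np.nan, "COHESION": np.nan,
            "DIVISION": np.nan, "SPLIT": np.nan,
        }
    class_area = areas.sum()
    lsi = 0.25 * perims.sum() / math.sqrt(class_area)
    if A > 1:
        cohesion = (
            100.0
            * (1.0 - perims.sum() / (perims * np.sqrt(areas)).sum())
            / (1.0 - 1.0 / math.sqrt(A))
        )
    else:
        cohesion = np.nan
    division = 1.0 - float(((areas / A) ** 2).sum())
    split = A**2 / float((areas**2).sum())
    return {
        "CA": class_area * cell_area_ha,
        "LPI": 100.0 * areas.max() / A,
        "LSI": lsi,
        "COHESION": cohesion,
        "DIVISION": division,
        "SPLIT": split,
    }


def diversity_metrics(
    window: np.ndarray, valid: np.ndarray | None = None
) -> dict:
    """CONTAG, SHDI, SHEI over the class mosaic of a window.

    Adjacencies for CONTAG are 4-neighbour and double-counted, both cells
    inside the window.  A single-class window has SHDI = 0, SHEI = 0 and
    CONTAG = 100 (perfect aggregation).
    """
    window = np.asarray(window)
    valid = np.ones(window.shape, bool) if valid is None else valid
    vals = window[valid]
    if vals.size == 0:
        raise ValueError("empty analysis window")
    classes, counts = np.unique(vals, return_counts=True)
    P = counts / counts.sum()
    shdi = float(-(P * np.log(P)).sum())
    m = len(classes)
    shei = shdi / math.log(m) if m > 1 else 0.0
    if m == 1:
        return {"CONTAG": 100.0, "SHDI": shdi, "SHEI": shei}

    # double-counted 4-neighbour adjacency table among valid cells
    g = np.zeros((m, m))
    index = {c: k for k, c in enumerate(classes)}
    for ax in (0, 1):
        a = np.take(window, range(window.shape[ax] - 1), axis=ax)
        b = np.take(window, range(1, window.shape[ax]), axis=ax)
        va = np.take(valid, range(valid.shape[ax] - 1), axis=ax)
        vb = np.take(valid, range(1, valid.shape[ax]), axis=ax)
        ok = va & vb
        for ca, cb in zip(a[ok].ravel(), b[ok].ravel()):
            i, k = index[ca], index[cb]
            g[i, k] += 1
            g[k, i] += 1

    total = 0.0
    for i in range(m):
        gi = g[i].sum()
        if gi == 0:
            continue
        for k in range(m):
            q = P[i] * g[i, k] / gi
            if q > 0:
                total += q * math.log(q)
    contag = (1.0 + total / (2.0 * math.log(m))) * 100.0
    return {"CONTAG": contag, "SHDI": shdi, "SHEI": shei}


def source_metrics(
    landuse: LandUseRaster,
    sources: SourceSet,
    margin_cells: int = 0,
) -> pd.DataFrame:
    """Per-source metrics table over each source's bounding clip.

    The window is the patch's bounding box (optionally padded by
    ``margin_cells``) masked to the patch polygon when ``margin_cells`` is 0,
    or taken whole when a margin is requested; the class of interest is the
    patch's dominant land-use class.
    """
    rows = []
    lu = landuse.values
    for p in sources.patches:
        r0, c0 = p.pixel_set.min(axis=0)
        r1, c1 = p.pixel_set.max(axis=0)
        r0 = max(r0 - margin_cells, 0)
        c0 = max(c0 - margin_cells, 0)
        r1 = min(r1 + margin_cells, lu.shape[0] - 1)
        c1 = min(c1 + margin_cells, lu.shape[1] - 1)
        window = lu[r0: r1 + 1, c0: c1 + 1]
        if margin_cells == 0:
            valid = np.zeros(window.shape, bool)
            valid[p.pixel_set[:, 0] - r0, p.pixel_set[:, 1] - c0] = True
        else:
            valid = window != landuse.nodata
        cls = p.land_class if p.land_class > 0 else int(
            np.bincount(window[valid]).argmax()
        )
        rec = {"node": p.id}
        rec.update(
            patch_structure_metrics(
                window, cls, valid, cell_area_ha=landuse.cell_area_ha
            )
        )
        rec.update(diversity_metrics(window, valid))
        rec["dPC"] = sources.dPC.get(p.id, np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)
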