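"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — pure-Python BFS flood fills,
exhaustive distance scans, path enumeration, dense linear algebra — and
shares no code with the package implementation it cross-checks.
"""

from __future__ import annotations

import heapq
import itertools
import math
from collections import deque

import numpy as np

# ---------------------------------------------------------------------------
# MSPA oracle

NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
NEIGH4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def _components(cells: set, neigh) -> list[set]:
    cells = set(cells)
    comps = []
    while cells:
        seed = cells.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            r, c = queue.popleft()
            for dr, dc in neigh:
                nb = (r + dr, c + dc)
                if nb in cells:
                    cells.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def _min_dist(cell, targets) -> float:
    if not targets:
        return math.inf
    r, c = cell
    return min(math.hypot(r - tr, c - tc) for tr, tc in targets)


def mspa_oracle(mask: np.ndarray, edge_width: int = 1, connectivity: int = 8):
    """Brute-force MSPA labels: background/core/islet/edge/perforation/connector.

    Implements the documented rule set by exhaustive distance computation
    and BFS flood fill; connector subtypes are not distinguished.
    """
    rows, cols = mask.shape
    fg = {(r, c) for r in range(rows) for c in range(cols) if mask[r, c]}
    # background includes a 1-ring pad, which contains the exact nearest
    # outside cell of the infinite exterior for every inside cell
    bg = {
        (r, c)
        for r in range(-1, rows + 1)
        for c in range(-1, cols + 1)
        if (r, c) not in fg
    }
    neigh_fg = NEIGH8 if connectivity == 8 else NEIGH4
    neigh_bg = NEIGH4 if connectivity == 8 else NEIGH8

    out = {}
    core = {c for c in fg if _min_dist(c, bg) > edge_width}

    bg_comps = _components(bg, neigh_bg)
    outside = set()
    holes = set()
    for comp in bg_comps:
        on_pad = any(
            r < 0 or r >= rows or c < 0 or c >= cols for r, c in comp
        )
        (outside if on_pad else holes).update(comp)

    fg_comps = _components(fg, neigh_fg)
    for comp in fg_comps:
        has_core = bool(comp & core)
        for cell in comp:
            if cell in core:
                out[cell] = "core"
                continue
            if not has_core:
                out[cell] = "islet"
                continue
            if connectivity == 8:
                near_core = any(
                    max(abs(cell[0] - r), abs(cell[1] - c)) <= edge_width
                    for r, c in core
                )
            else:
                near_core = any(
                    abs(cell[0] - r) + abs(cell[1] - c) <= edge_width
                    for r, c in core
                )
            if not near_core:
                out[cell] = "connector"
                continue
            d_out = _min_dist(cell, outside)
            d_hole = _min_dist(cell, holes)
            if d_out <= edge_width and d_out <= d_hole:
                out[cell] = "edge"
            elif d_hole <= edge_width:
                out[cell] = "perforation"
            else:
                out[cell] = "edge"
    return out


# ---------------------------------------------------------------------------
# max-product dispersal paths by exhaustive enumeration (n <= ~7)

def max_product_enumeration(direct_p: np.ndarray) -> np.ndarray:
    n = direct_p.shape[0]
    pstar = np.array(direct_p, dtype=float)
    np.fill_diagonal(pstar, 1.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = direct_p[i, j]
            others = [k for k in range(n) if k not in (i, j)]
            for r in range(1, len(others) + 1):
                for mids in itertools.permutations(others, r):
                    seq = [i, *mids, j]
                    prod = 1.0
                    for a, b in zip(seq, seq[1:]):
                        prod *= direct_p[a, b]
                    best = max(best, prod)
            pstar[i, j] = best
    return pstar


def pc_double_sum(areas, pstar, A_L) -> float:
    total = 0.0
    n = len(areas)
    for i in range(n):
        for j in range(n):
            total += areas[i] * areas[j] * pstar[i, j]
    return total / A_L**2


# ---------------------------------------------------------------------------
# lattice Dijkstra oracle

def lattice_dijkstra(resistance: np.ndarray, cell_size: float, sources) -> np.ndarray:
    """Textbook multi-source Dijkstra on the 8-connected lattice."""
    rows, cols = resistance.shape
    dist = np.full((rows, cols), math.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in NEIGH8:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                continue
            step = cell_size * (math.sqrt(2) if dr and dc else 1.0)
            nd = d + 0.5 * (resistance[r, c] + resistance[nr, nc]) * step
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                heapq.heappush(heap, (nd, nr, nc))
    return dist


# ---------------------------------------------------------------------------
# graph indicator oracles (tiny graphs)

def bfs_distances(adj: dict, start):
    dist = {start: 0}
    queue = deque([start])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def graph_oracle(nodes, edges) -> dict:
    """Degree, clustering, closeness, betweenness, eccentricity, eigenvector,
    pagerank and average path length from first definitions."""
    nodes = sorted(nodes)
    n = len(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    degree = {v: len(adj[v]) for v in nodes}
    clustering = {}
    for v in nodes:
        k = degree[v]
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1
            for a, b in itertools.combinations(sorted(adj[v]), 2)
            if b in adj[a]
        )
        clustering[v] = 2.0 * links / (k * (k - 1))

    closeness, eccentricity = {}, {}
    apl_total, apl_pairs = 0, 0
    for v in nodes:
        dist = bfs_distances(adj, v)
        reach = len(dist) - 1
        tot = sum(dist.values())
        closeness[v] = reach / tot if tot > 0 else 0.0
        eccentricity[v] = max(dist.values()) if reach else 0
        for u, d in dist.items():
            if u > v:
                apl_total += d
                apl_pairs += 1
    apl = apl_total / apl_pairs if apl_pairs else math.nan

    # betweenness by enumerating all shortest paths
    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / len(paths)
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        betweenness = {v: b * scale for v, b in betweenness.items()}

    a = np.zeros((n, n))
    index = {v: i for i, v in enumerate(nodes)}
    for u, v in edges:
        a[index[u], index[v]] = a[index[v], index[u]] = 1
    eigen = {}
    if a.any():
        w, vecs = np.linalg.eigh(a)
        vec = np.abs(vecs[:, np.argmax(w)])
        vec = vec / vec.max()
        eigen = {v: vec[index[v]] for v in nodes}
    else:
        eigen = {v: 0.0 for v in nodes}

    # PageRank: power iteration on the dense Google matrix
    alpha = 0.85
    p = np.full(n, 1.0 / n)
    m = np.zeros((n, n))
    for v in nodes:
        i = index[v]
        if degree[v]:
            for u in adj[v]:
                m[index[u], i] = 1.0 / degree[v]
        else:
            m[:, i] = 1.0 / n
    for _ in range(5000):
        nxt = alpha * m @ p + (1 - alpha) / n
        if np.abs(nxt - p).sum() < 1e-13:
            p = nxt
            break
        p = nxt
    pagerank = {v: p[index[v]] for v in nodes}

    return {
        "degree": degree,
        "clustering": clustering,
        "closeness": closeness,
        "betweenness": betweenness,
        "eccentricity": eccentricity,
        "eigenvector": eigen,
        "pagerank": pagerank,
        "average_path_length": apl,
    }


def _all_shortest_paths(adj, s, t):
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []
    stack = [(t, [t])]
    while stack:
        v, path = stack.pop()
        if v == s:
            paths.append(path)
            continue
        for u in adj[v]:
            if dist.get(u, math.inf) == dist[v] - 1:
                stack.append((u, [u, *path]))
    return paths


def modularity_by_hand(nodes, edges, labels) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) over communities."""
    m = len(edges)
    if m == 0:
        return 0.0
    comms = set(labels.values())
    q = 0.0
    degree = {v: 0 for v in nodes}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    for c in comms:
        members = {v for v in nodes if labels[v] == c}
        e_c = sum(1 for u, v in edges if u in members and v in members)
        d_c = sum(degree[v] for v in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# landscape metric oracle (independent bookkeeping)

def landscape_oracle(window: np.ndarray, cls, valid=None) -> dict:
    """CA (cells), LPI, LSI, COHESION, DIVISION, SPLIT, CONTAG, SHDI, SHEI
    by direct formula evaluation with python loops."""
    rows, cols = window.shape
    valid = np.ones_like(window, bool) if valid is None else valid
    cells = {
        (r, c) for r in range(rows) for c in range(cols)
        if valid[r, c] and window[r, c] == cls
    }
    A = int(valid.sum())
    patches = _components(cells, NEIGH8)
    out = {}
    if patches:
        areas, perims = [], []
        for patch in patches:
            areas.append(len(patch))
            perim = 0
            for r, c in patch:
                for dr, dc in NEIGH4:
                    if (r + dr, c + dc) not in patch:
                        perim += 1
            perims.append(perim)
        class_area = sum(areas)
        out["CA"] = class_area
        out["LPI"] = 100.0 * max(areas) / A
        out["LSI"] = 0.25 * sum(perims) / math.sqrt(class_area)
        num = sum(perims)
        den = sum(p * math.sqrt(a) for p, a in zip(perims, areas))
        out["COHESION"] = (
            100.0 * (1 - num / den) / (1 - 1 / math.sqrt(A)) if A > 1 else math.nan
        )
        out["DIVISION"] = 1.0 - sum((a / A) ** 2 for a in areas)
        out["SPLIT"] = A**2 / sum(a**2 for a in areas)

    vals = [window[r, c] for r in range(rows) for c in range(cols) if valid[r, c]]
    classes = sorted(set(vals))
    P = {k: vals.count(k) / len(vals) for k in classes}
    shdi = -sum(p * math.log(p) for p in P.values() if p > 0)
    out["SHDI"] = shdi
    out["SHEI"] = shdi / math.log(len(classes)) if len(classes) > 1 else 0.0
    if len(classes) == 1:
        out["CONTAG"] = 100.0
        return out
    g = {(i, k): 0 for i in classes for k in classes}
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            for dr, dc in NEIGH4:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and valid[nr, nc]:
                    g[(window[r, c], window[nr, nc])] += 1
    total = 0.0
    for i in classes:
        gi = sum(g[(i, k)] for k in classes)
        if gi == 0:
            continue
        for k in classes:
            q = P[i] * g[(i, k)] / gi
            if q > 0:
                total += q * math.log(q)
    out["CONTAG"] = (1 + total / (2 * math.log(len(classes)))) * 100.0
    return out
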