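"""Natural breaks, resistance surfaces, cost distance and corridors."""

import math

import numpy as np
import pytest

from greenet.connectivity import Patch, SourceSet
from greenet.rasters import AlignmentError, ConfigError, FactorRaster
from greenet.resistance import (
    ResistanceSurface,
    build_resistance,
    cost_distance,
    jenks_breaks,
    jenks_grade,
    least_cost_corridors,
    path_cost,
)

from oracles import lattice_dijkstra


def factor(values, name="dem"):
    return FactorRaster(values=np.asarray(values, float), name=name)


class TestJenks:
    def test_obvious_gap(self):
        assert jenks_breaks(np.array([1, 2, 3, 10, 11, 12.0]), 2) == [3.0]

    def test_grades_and_inversion(self):
        f = factor([[1, 2, 3], [10, 11, 12]])
        assert jenks_grade(f, 2).tolist() == [[1, 1, 1], [2, 2, 2]]
        assert jenks_grade(f, 2, inverted=True).tolist() == [[2, 2, 2], [1, 1, 1]]

    def test_minimizes_within_class_ssd(self):
        # exhaustive check over all single-break positions
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = np.sort(rng.normal(size=12))
            (brk,) = jenks_breaks(x, 2)
            k = int(np.searchsorted(x, brk, side="right"))

            def ssd(v):
                return ((v - v.mean()) ** 2).sum() if len(v) else 0.0

            best = min(ssd(x[:i]) + ssd(x[i:]) for i in range(1, len(x)))
            assert ssd(x[:k]) + ssd(x[k:]) == pytest.approx(best, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigError):
            jenks_breaks(np.full(10, 3.0), 2)
        with pytest.raises(ConfigError):
            jenks_breaks(np.arange(10.0), 1)


class TestBuildResistance:
    def _graded(self, fill):
        return {n: np.full((3, 3), fill, dtype=float) for n in (
            "dem", "slope", "ndvi", "mndwi", "lucc",
            "pop_density", "water_density", "road_density")}

    def test_equal_weights_uniform(self):
        s = build_resistance(self._graded(3), cell_size=30.0)
        assert np.allclose(s.values, 3.0)

    def test_projection_single_weight(self):
        graded = self._graded(2)
        graded["slope"] = np.full((3, 3), 5.0)
        weights = {n: 0.0 for n in graded}
        weights["slope"] = 1.0
        s = build_resistance(graded, weights, cell_size=30.0)
        assert np.allclose(s.values, 5.0)

    def test_hand_computed_weighted_sum(self):
        graded = {n: np.full((2, 2), g, dtype=float)
                  for n, g in zip(("dem", "slope"), (2, 4))}
        s = build_resistance(graded, {"dem": 0.25, "slope": 0.75}, cell_size=30.0)
        assert np.allclose(s.values, 0.25 * 2 + 0.75 * 4)

    def test_misaligned_rejected(self):
        graded = self._graded(1)
        graded["dem"] = np.ones((4, 4))
        with pytest.raises(AlignmentError):
            build_resistance(graded, cell_size=30.0)


class TestCostDistance:
    def test_uniform_surface_axial_cost(self):
        s = ResistanceSurface(values=np.full((7, 7), 3.0), cell_size=30.0)
        cd = cost_distance(s, np.array([[3, 3]]))
        assert cd[3, 3] == 0.0
        for k in (1, 2, 3):
            assert cd[3, 3 + k] == pytest.approx(3.0 * k * 30.0)

    def test_linearity_in_surface(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(1, 5, (6, 6))
        s1 = ResistanceSurface(values=v, cell_size=10.0)
        s2 = ResistanceSurface(values=2 * v, cell_size=10.0)
        c1 = cost_distance(s1, np.array([[0, 0]]))
        c2 = cost_distance(s2, np.array([[0, 0]]))
        assert np.allclose(c2, 2 * c1)

    def test_matches_dijkstra_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            v = rng.uniform(0.5, 9.0, (15, 15))
            src = [(int(rng.integers(15)), int(rng.integers(15)))]
            s = ResistanceSurface(values=v, cell_size=30.0)
            got = cost_distance(s, np.array(src))
            want = lattice_dijkstra(v, 30.0, src)
            assert np.allclose(got, want)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(23)
        v = rng.uniform(1, 4, (10, 10))
        s = ResistanceSurface(values=v, cell_size=30.0)
        a, b, c = (0, 0), (5, 5), (9, 9)
        dab = cost_distance(s, np.array([a]))[b]
        dbc = cost_distance(s, np.array([b]))[c]
        dac = cost_distance(s, np.array([a]))[c]
        assert dac <= dab + dbc + 1e-9


def _sources_from_blocks(blocks, cell_size=30.0):
    patches = []
    for pid, cells in blocks.items():
        arr = np.array(cells)
        patches.append(Patch(
            id=pid, pixel_set=arr, area_m2=len(arr) * cell_size**2,
            centroid=(arr[:, 1].mean() * cell_size, -arr[:, 0].mean() * cell_size),
        ))
    return SourceSet(patches=patches, dPC={p.id: 1.0 for p in patches})


class TestCorridors:
    def test_two_sources_uniform_surface(self):
        s = ResistanceSurface(values=np.ones((9, 21)), cell_size=30.0)
        sources = _sources_from_blocks({1: [[4, 2]], 2: [[4, 18]]})
        (corr,) = least_cost_corridors(s, sources)
        assert corr.src_id == 1 and corr.dst_id == 2
        assert corr.path[0] == (4, 2) and corr.path[-1] == (4, 18)
        assert all(r == 4 for r, _ in corr.path)  # straight segment
        assert corr.cost == pytest.approx(16 * 30.0)

    def test_collinear_sources_cost_ordering(self):
        s = ResistanceSurface(values=np.ones((5, 31)), cell_size=30.0)
        sources = _sources_from_blocks({1: [[2, 1]], 2: [[2, 15]], 3: [[2, 29]]})
        corridors = least_cost_corridors(s, sources)
        by_pair = {(c.src_id, c.dst_id): c for c in corridors}
        assert by_pair[(1, 2)].cost < by_pair[(1, 3)].cost
        assert by_pair[(2, 3)].cost < by_pair[(1, 3)].cost

    def test_path_cost_audit(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.5, 5.0, (12, 12))
        s = ResistanceSurface(values=v, cell_size=30.0)
        sources = _sources_from_blocks(
            {1: [[1, 1], [1, 2]], 2: [[10, 10], [10, 9]]}
        )
        for corr in least_cost_corridors(s, sources):
            assert path_cost(s, corr.path) == pytest.approx(
                corr.cost, rel=1e-9
            )

    def test_mediated_pair_pruned(self):
        # three collinear point sources: the end-to-end path runs through
        # the middle source and is dropped under drop_mediated
        s = ResistanceSurface(values=np.ones((5, 31)), cell_size=30.0)
        sources = _sources_from_blocks({1: [[2, 1]], 2: [[2, 15]], 3: [[2, 29]]})
        kept = least_cost_corridors(s, sources, drop_mediated=True)
        pairs = {(c.src_id, c.dst_id) for c in kept}
        assert pairs == {(1, 2), (2, 3)}

    def test_corridor_count_bound(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(1, 3, (20, 20))
        s = ResistanceSurface(values=v, cell_size=30.0)
        sources = _sources_from_blocks(
            {1: [[2, 2]], 2: [[2, 17]], 3: [[17, 2]], 4: [[17, 17]]}
        )
        corridors = least_cost_corridors(s, sources)
        assert len(corridors) <= 4 * 3 // 2
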