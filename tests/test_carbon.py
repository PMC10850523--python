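"""Carbon accounting: pool sums, conservation, buffer profiles."""

import numpy as np
import pandas as pd
import pytest

from greenet.carbon import (
    CarbonDensityTable,
    CarbonRaster,
    buffer_mean_carbon,
    carbon_raster,
    node_source_carbon_table,
    source_mask,
    zone_total,
)
from greenet.connectivity import Patch, SourceSet
from greenet.rasters import ConfigError, LandUseRaster
from greenet.synthetic import default_carbon_table, toy_fixture


def landuse_30m(values):
    return LandUseRaster(values=np.asarray(values, dtype=np.int32), cell_size=30.0)


class TestCarbonRaster:
    def test_single_cell_worked_example(self):
        # pools (30, 20, 80, 5) Mg/ha on a 30 m cell: 135 x 0.09 = 12.15 Mg
        table = CarbonDensityTable(densities={2: (30.0, 20.0, 80.0, 5.0)})
        lu = landuse_30m([[2]])
        c = carbon_raster(lu, table)
        assert c.values[0, 0] == pytest.approx(12.15)

    def test_all_zero_table(self):
        table = CarbonDensityTable(densities={1: (0, 0, 0, 0), 2: (0, 0, 0, 0)})
        lu = toy_fixture("uniform_block")
        assert carbon_raster(lu, table).total() == 0.0

    def test_mixed_fixture_cellwise_oracle(self):
        table = CarbonDensityTable(
            densities={1: (1.0, 2.0, 3.0, 4.0), 2: (10.0, 0.0, 5.0, 0.5)}
        )
        lu = landuse_30m([[1, 2, 1], [2, 2, 1], [1, 1, 2]])
        c = carbon_raster(lu, table)
        dens = {1: 10.0, 2: 15.5}
        expected = sum(
            dens[int(v)] * 0.09 for v in lu.values.ravel()
        )
        assert c.total() == pytest.approx(expected)

    def test_missing_class_reported(self):
        table = CarbonDensityTable(densities={1: (1, 1, 1, 1)})
        with pytest.raises(ConfigError, match=r"\[2\]"):
            carbon_raster(landuse_30m([[1, 2]]), table)

    def test_conservation_over_partition(self):
        lu = toy_fixture("three_patch_toy")
        c = carbon_raster(lu, default_carbon_table())
        zones = np.arange(lu.values.size).reshape(lu.shape) % 4
        parts = sum(zone_total(c, zones == k) for k in range(4))
        assert parts == pytest.approx(c.total(), rel=1e-9)

    def test_doubling_densities_doubles_stock(self):
        table = default_carbon_table()
        doubled = CarbonDensityTable(
            densities={k: tuple(2 * x for x in v)
                       for k, v in table.densities.items()}
        )
        lu = toy_fixture("ring_with_hole")
        c1 = carbon_raster(lu, table)
        c2 = carbon_raster(lu, doubled)
        assert np.allclose(c2.values, 2 * c1.values)


class TestBufferProfiles:
    def test_uniform_raster_flat_profile(self):
        c = CarbonRaster(values=np.full((21, 21), 2.0), cell_size=30.0)
        mask = np.zeros((21, 21), bool)
        mask[10, 10] = True
        prof = buffer_mean_carbon(c, mask, (60.0, 120.0, 180.0))
        assert prof.mean_carbon == pytest.approx([2.0, 2.0, 2.0])
        assert not prof.monotone_decreasing

    def test_decaying_core_strictly_decreasing(self):
        values = np.zeros((20, 20))
        values[9:11, 9:11] = 100.0
        c = CarbonRaster(values=values, cell_size=30.0)
        mask = np.zeros((20, 20), bool)
        mask[9:11, 9:11] = True
        prof = buffer_mean_carbon(c, mask, (30.0, 60.0, 90.0, 120.0))
        assert prof.monotone_decreasing
        assert all(a > b for a, b in
                   zip(prof.mean_carbon, prof.mean_carbon[1:]))

    def test_hand_computed_means(self):
        values = np.zeros((9, 9))
        values[4, 4] = 9.0
        c = CarbonRaster(values=values, cell_size=30.0)
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        prof = buffer_mean_carbon(c, mask, (30.0,))
        # disk of radius 1 cell: center + 4 axial neighbours
        assert prof.mean_carbon[0] == pytest.approx(9.0 / 5.0)

    def test_cumulative_nesting(self):
        rng = np.random.default_rng(8)
        c = CarbonRaster(values=rng.uniform(0, 5, (15, 15)), cell_size=30.0)
        mask = np.zeros((15, 15), bool)
        mask[7, 7] = True
        dist = np.array([30.0, 60.0, 90.0, 120.0])
        counts = [
            ((np.indices((15, 15)) - 7) ** 2).sum(axis=0) <= (d / 30.0) ** 2
            for d in dist
        ]
        ns = [m.sum() for m in counts]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_bad_inputs(self):
        c = CarbonRaster(values=np.ones((5, 5)), cell_size=30.0)
        with pytest.raises(ConfigError):
            buffer_mean_carbon(c, np.zeros((5, 5), bool))
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(ConfigError):
            buffer_mean_carbon(c, mask, (60.0, 30.0))


class TestNodeSourceTable:
    def _sources(self, cells, pid=1):
        arr = np.array(cells)
        patch = Patch(
            id=pid, pixel_set=arr, area_m2=len(arr) * 900.0,
            centroid=((arr[:, 1].mean() + 0.5) * 30.0,
                      -(arr[:, 0].mean() + 0.5) * 30.0),
            land_class=2,
        )
        return SourceSet(patches=[patch], dPC={pid: 1.0})

    def test_uniform_world_zero_difference(self):
        c = CarbonRaster(values=np.full((20, 20), 3.0), cell_size=30.0)
        sources = self._sources([[9, 9], [9, 10], [10, 9], [10, 10]])
        df = node_source_carbon_table(sources, c, (30.0, 60.0))
        assert len(df) == 1
        assert df.loc[0, "carbon_difference"] == pytest.approx(0.0)
        assert not df.loc[0, "node_monotone"]

    def test_row_count_matches_sources(self):
        c = CarbonRaster(values=np.ones((30, 30)), cell_size=30.0)
        patches = [
            Patch(id=i, pixel_set=np.array([[5 * i, 5 * i]]), area_m2=900.0,
                  centroid=((5 * i + 0.5) * 30.0, -(5 * i + 0.5) * 30.0))
            for i in (1, 2, 3)
        ]
        sources = SourceSet(patches=patches, dPC={i: 1.0 for i in (1, 2, 3)})
        df = node_source_carbon_table(sources, c, (30.0,))
        assert list(df["node"]) == [1, 2, 3]

    def test_monotone_flags_on_decaying_core(self):
        values = np.zeros((21, 21))
        values[8:13, 8:13] = 50.0
        c = CarbonRaster(values=values, cell_size=30.0)
        cells = [[r, col] for r in range(9, 12) for col in range(9, 12)]
        sources = self._sources(cells)
        df = node_source_carbon_table(sources, c, (30.0, 60.0, 90.0, 120.0))
        assert bool(df.loc[0, "node_monotone"]) or bool(df.loc[0, "source_monotone"])

    def test_source_mask_roundtrip(self):
        patch = Patch(id=1, pixel_set=np.array([[1, 2], [3, 4]]),
                      area_m2=1800.0, centroid=(0.0, 0.0))
        mask = source_mask((5, 5), patch)
        assert mask.sum() == 2 and mask[1, 2] and mask[3, 4]
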