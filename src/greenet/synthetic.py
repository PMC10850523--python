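"""Synthetic landscapes with the spatial structure the pipeline assumes.

Real applications of this pipeline start from satellite land-cover products,
population grids and OSM-derived density layers.  This module generates
stand-ins with the properties that matter to the method — spatially clumped
categorical patches, smooth correlated factor fields, and a per-class carbon
density table — so the whole pipeline can run from seeded fixtures.

The default configuration emulates a temperate agricultural plain with
forested uplands at a regional scale: a 200 x 200 grid of 1 km cells
(a 200 km x 200 km domain), forest/grass/water green space over roughly half
the landscape, and a dozen compact forest massifs large enough to pass the
25 km^2 source-area gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .rasters import (
    DEFAULT_CLASS_TABLE,
    ConfigError,
    FactorRaster,
    LandUseRaster,
)

# fixed offsets deriving independent substreams from the one user seed
_STREAM_LANDUSE = 0
_STREAM_BLOBS = 101
_STREAM_FACTORS = 211

#: default class proportions: green space (forest+grass+water) ~ 0.5
DEFAULT_PROPORTIONS = {
    1: 0.30,  # cropland
    2: 0.30,  # forest
    3: 0.15,  # grassland
    4: 0.05,  # water
    5: 0.15,  # built
    6: 0.05,  # barren
}

DEFAULT_FACTOR_NOISE_SD = {
    "dem": 120.0,
    "slope": 0.5,
    "ndvi": 0.05,
    "mndwi": 0.05,
    "pop_density": 50.0,
    "water_density": 0.05,
    "road_density": 0.1,
}

#: ordinal recode of land-use classes used as the LUCC resistance factor
#: (low = permeable green space, high = hostile built surface)
LUCC_RECODE = {2: 1.0, 3: 2.0, 4: 3.0, 1: 4.0, 6: 5.0, 5: 6.0}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic-landscape generator.

    ``clumping`` is the Gaussian smoothing scale, in cells, applied to the
    per-class noise fields; larger values give larger coherent patches.
    ``n_source_blobs`` compact forest disks are stamped on top so that the
    landscape always contains core patches above the source-area gate.
    """

    seed: int = 0
    shape: tuple[int, int] = (200, 200)
    cell_size: float = 1000.0
    class_proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    clumping: float = 4.0
    n_source_blobs: int = 12
    blob_radius: tuple[int, int] = (3, 7)
    factor_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_NOISE_SD)
    )

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigError("class proportions must be non-negative")
        if self.clumping <= 0:
            raise ConfigError("clumping must be positive")
        unknown = set(self.class_proportions) - set(DEFAULT_CLASS_TABLE)
        if unknown:
            raise ConfigError(f"unknown class codes {sorted(unknown)}")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian random field smoothed at scale ``sigma``."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def generate_landuse(config: SyntheticConfig) -> LandUseRaster:
    """Generate a clumped categorical land-use raster.

    Each class gets an independent smoothed Gaussian field; cells take the
    argmax of field + per-class offset, with the offsets calibrated
    iteratively so realized class fractions track the requested proportions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _STREAM_LANDUSE)
    codes = [c for c, p in sorted(config.class_proportions.items()) if p > 0]
    targets = np.array([config.class_proportions[c] for c in codes])
    rows, cols = config.shape

    if len(codes) == 1:
        values = np.full(config.shape, codes[0], dtype=np.int32)
    else:
        fields = np.stack(
            [_smooth_field(rng, config.shape, config.clumping) for _ in codes]
        )
        offsets = np.log(targets)  # sensible start: log-proportion prior
        values = None
        for _ in range(80):
            labels = np.argmax(fields + offsets[:, None, None], axis=0)
            realized = np.bincount(labels.ravel(), minlength=len(codes)) / (
                rows * cols
            )
            offsets += 2.0 * (targets - realized)
            if np.abs(realized - targets).max() < 0.01:
                break
        values = np.array(codes, dtype=np.int32)[labels]

    values = _stamp_source_blobs(values, config)
    return LandUseRaster(values=values, cell_size=config.cell_size)


def _stamp_source_blobs(values: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Stamp compact disks of the dominant green class (forest by default)."""
    green = [c for c in (2, 3, 4) if config.class_proportions.get(c, 0) > 0]
    if not green or config.n_source_blobs <= 0:
        return values
    code = max(green, key=lambda c: config.class_proportions[c])
    rng = np.random.default_rng(config.seed + _STREAM_BLOBS)
    rows, cols = values.shape
    out = values.copy()
    rr, cc = np.mgrid[0:rows, 0:cols]
    lo, hi = config.blob_radius
    for _ in range(config.n_source_blobs):
        r0 = rng.integers(hi, max(rows - hi, hi + 1))
        c0 = rng.integers(hi, max(cols - hi, hi + 1))
        radius = int(rng.integers(lo, hi + 1))
        out[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = code
    return out


def generate_factors(
    landuse: LandUseRaster, config: SyntheticConfig
) -> list[FactorRaster]:
    """Generate the eight resistance-factor layers aligned to ``landuse``.

    DEM and its slope are smooth terrain surrogates with a NW-high trend;
    NDVI/MNDWI follow the vegetation and water classes plus smooth noise;
    LUCC is a deterministic ordinal recode of the classes; population, water
    and road densities are smooth fields anchored to built/water cells.
    """
    rng = np.random.default_rng(config.seed + _STREAM_FACTORS)
    rows, cols = landuse.shape
    sd = {**DEFAULT_FACTOR_NOISE_SD, **config.factor_noise_sd}
    sigma = max(config.clumping, 2.0)
    rr = np.linspace(1.0, 0.0, rows)[:, None]
    cc = np.linspace(1.0, 0.0, cols)[None, :]

    dem = 1000.0 + 350.0 * (0.6 * rr + 0.4 * cc) + sd["dem"] * _smooth_field(
        rng, landuse.shape, 2 * sigma
    )
    gy, gx = np.gradient(dem, landuse.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy))) + np.abs(
        sd["slope"] * _smooth_field(rng, landuse.shape, sigma)
    )

    lu = landuse.values
    ndvi_base = {1: 0.45, 2: 0.80, 3: 0.60, 4: 0.05, 5: 0.15, 6: 0.10}
    mndwi_base = {1: -0.30, 2: -0.40, 3: -0.35, 4: 0.70, 5: -0.20, 6: -0.25}
    ndvi = np.clip(
        _recode(lu, ndvi_base) + sd["ndvi"] * _smooth_field(rng, lu.shape, sigma),
        -1.0,
        1.0,
    )
    mndwi = np.clip(
        _recode(lu, mndwi_base) + sd["mndwi"] * _smooth_field(rng, lu.shape, sigma),
        -1.0,
        1.0,
    )
    lucc = _recode(lu, LUCC_RECODE, default=4.0)

    built = (lu == 5).astype(float)
    pop = 400.0 * ndimage.gaussian_filter(built, sigma, mode="reflect") + np.abs(
        sd["pop_density"] * _smooth_field(rng, lu.shape, sigma)
    )
    water = (lu == 4).astype(float)
    water_density = ndimage.gaussian_filter(water, sigma, mode="reflect") + np.abs(
        sd["water_density"] * _smooth_field(rng, lu.shape, sigma)
    )
    road = 0.6 * pop / max(pop.max(), 1e-12) + np.abs(
        sd["road_density"] * _smooth_field(rng, lu.shape, sigma)
    )

    arrays = {
        "dem": dem,
        "slope": slope,
        "ndvi": ndvi,
        "mndwi": mndwi,
        "lucc": lucc,
        "pop_density": pop,
        "water_density": water_density,
        "road_density": road,
    }
    return [
        FactorRaster(
            values=a, name=n, cell_size=landuse.cell_size, origin=landuse.origin
        )
        for n, a in arrays.items()
    ]


def _recode(values: np.ndarray, table: dict[int, float], default: float = 0.0):
    out = np.full(values.shape, default, dtype=np.float64)
    for code, v in table.items():
        out[values == code] = v
    return out


def default_carbon_table():
    """Configurable placeholder carbon densities (Mg/ha) per land-use class.

    The four pools are above-ground, below-ground, soil and dead organic
    matter.  The values are plausible for a temperate North-China landscape
    but are explicitly placeholders: any real application must substitute a
    regionally calibrated density database.
    """
    from .carbon import CarbonDensityTable

    return CarbonDensityTable(
        densities={
            1: (5.7, 1.2, 80.0, 0.5),  # cropland
            2: (35.0, 8.5, 120.0, 2.5),  # forest
            3: (3.0, 6.8, 90.0, 0.8),  # grassland
            4: (0.1, 0.0, 40.0, 0.0),  # water: above-ground ~ 0
            5: (1.2, 0.3, 45.0, 0.1),  # built
            6: (0.5, 0.1, 30.0, 0.1),  # barren
        }
    )


# ---------------------------------------------------------------------------
# hand-coded toy fixtures (forest code 2 on cropland code 1, 30 m cells)

def _grid_from_mask(mask: np.ndarray) -> LandUseRaster:
    values = np.where(mask, 2, 1).astype(np.int32)
    return LandUseRaster(values=values, cell_size=30.0)


def _single_pixel() -> LandUseRaster:
    m = np.zeros((7, 7), bool)
    m[3, 3] = True
    return _grid_from_mask(m)


def _ring_with_hole() -> LandUseRaster:
    # 11x11: forest ring of thickness 3 enclosing a 3x3 background hole
    m = np.zeros((11, 11), bool)
    m[1:10, 1:10] = True
    m[4:7, 4:7] = False
    return _grid_from_mask(m)


def _two_cores_bridge() -> LandUseRaster:
    # two 5x5 blocks joined by a 1-cell-wide, 3-cell-long path
    m = np.zeros((9, 15), bool)
    m[2:7, 1:6] = True
    m[2:7, 9:14] = True
    m[4, 6:9] = True
    return _grid_from_mask(m)


def _uniform_block() -> LandUseRaster:
    return _grid_from_mask(np.ones((10, 10), bool))


def _three_patch_toy() -> LandUseRaster:
    # three separated blocks of decreasing size: 5x5, 4x4, 2x2
    m = np.zeros((14, 14), bool)
    m[1:6, 1:6] = True
    m[8:12, 2:6] = True
    m[3:5, 10:12] = True
    return _grid_from_mask(m)


FIXTURES = {
    "single_pixel": _single_pixel,
    "ring_with_hole": _ring_with_hole,
    "two_cores_bridge": _two_cores_bridge,
    "uniform_block": _uniform_block,
    "three_patch_toy": _three_patch_toy,
}


def toy_fixture(name: str) -> LandUseRaster:
    """Return a hand-coded <= 20x20 fixture with a documented expected outcome."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
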