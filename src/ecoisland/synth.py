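"""Seeded generator of a virtual tropical island.

The generator emulates the statistical structure a coastal-lowland /
mountainous-interior tropical island analysis assumes, so that every
downstream stage (landscape pattern, the four service models, change
accounting, driver ranking) can be exercised end-to-end without any
external download:

* a radially decreasing DEM, low along the coast and peaking in a
  500-800 m interior band;
* a forest-dominated land-use mosaic (~63 % forest, ~26 % arable,
  ~2.5 % built-up at the first epoch) whose built-up class expands
  monotonically along the coast over seven epochs;
* orographic monthly precipitation in the 1000-2000 mm yr-1 band and
  temperature lapsed -0.6 degC per 100 m from a 22-27 degC coastal mean;
* soil physical layers, class-conditioned NDVI, and a 12-layer coarse
  driver stack (AET, DEF, PET, RO, SOIL, SRAD, TMN, TMX, VPD, VS, PRE,
  NDVI) whose internal identities (DEF = PET - AET, RO <= PRE) hold by
  construction.

The causal structure is planted: a vegetation-condition field mixes the
standardized driver fields with configurable weights in which
precipitation is strictly the largest, and precipitation additionally
enters the water balance and rainfall erosivity directly.  Recovering
precipitation as the top-ranked driver of every service is therefore the
pipeline's parameter-recovery surface.

Everything is deterministic given the scenario's single integer seed:
each layer draws from its own child of ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import (
    CATEGORICAL_NODATA,
    CategoricalRaster,
    GridSpec,
    LANDUSE_LEGEND,
    Raster,
    align,
)

# class codes
ARABLE, FOREST, GRASSLAND, WATER, BUILTUP, BARELAND = 1, 2, 3, 4, 5, 6

DRIVER_NAMES = (
    "AET", "DEF", "PET", "RO", "SOIL", "SRAD",
    "TMN", "TMX", "VPD", "VS", "PRE", "NDVI",
)

# stream ids for per-layer child seeds
_S_DEM, _S_LANDUSE, _S_CLIMATE, _S_SOIL, _S_NDVI, _S_DRIVERS = range(6)

#: monsoon monthly precipitation weights (sum exactly 1 after normalization)
_MONTH_P_W = np.array([.02, .02, .03, .05, .08, .10, .12, .14, .16, .14, .09, .05])
_MONTH_P_W = _MONTH_P_W / _MONTH_P_W.sum()
#: seasonal offsets (degC) added to the annual-mean temperature
_MONTH_T_OFF = np.array([-4.5, -4.0, -2.5, -0.5, 1.5, 3.0, 3.8, 3.5, 2.3, 0.5, -1.5, -3.5])
#: monthly mean shortwave radiation, MJ m-2 day-1
_MONTH_SRAD = np.array([13., 14., 16., 17., 17., 16., 16., 15., 14., 13., 12., 12.])
_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)


def _default_weights() -> dict[str, float]:
    # precipitation strictly the maximum: the planted dominant driver
    return {
        "PRE": 1.0, "SOIL": 0.40, "AET": 0.25, "TMX": 0.18, "TMN": 0.15,
        "VPD": 0.10, "RO": 0.08, "PET": 0.08, "SRAD": 0.08, "DEF": 0.06,
        "VS": 0.05,
    }


def _default_targets() -> dict[int, float]:
    return {
        FOREST: 0.630, ARABLE: 0.260, GRASSLAND: 0.040,
        WATER: 0.030, BUILTUP: 0.025, BARELAND: 0.015,
    }


@dataclass
class IslandScenario:
    """Full parameterization of the virtual island (one seed -> one world)."""

    n_rows: int = 300
    n_cols: int = 300
    cell_size: float = 30.0
    years: Sequence[int] = (1980, 1990, 1995, 2000, 2005, 2010, 2015)
    seed: int = 0

    # land use
    class_targets: dict[int, float] = field(default_factory=_default_targets)
    urban_growth_rate: float = 0.0025   # island fraction converted per epoch step
    coastal_band_m: float = 3000.0      # urban growth restricted to this coastal band
    reserves: Sequence[tuple[float, float, float]] = (
        # (row frac, col frac, radius frac) interior circles that never change class
        (0.50, 0.50, 0.060), (0.38, 0.42, 0.045), (0.60, 0.40, 0.045),
        (0.42, 0.62, 0.045), (0.62, 0.60, 0.045),
    )

    # terrain
    island_radius_frac: float = 0.48    # of the shorter grid side; outside is sea
    peak_elevation_m: float = 650.0     # inside the 500-800 m interior band
    dem_noise_amp_m: float = 8.0
    noise_sigma_cells: float = 8.0

    # climate
    coastal_precip_mm: float = 1350.0
    precip_orographic_mm_per_m: float = 0.3   # +30 mm per 100 m elevation
    precip_noise_amp_mm: float = 250.0
    precip_epoch_cv: float = 0.03
    coastal_tmean_c: float = 24.5             # in the 22-27 degC band
    lapse_c_per_m: float = 0.006              # -0.6 degC per 100 m
    diurnal_range_c: float = 8.0
    bump_1995: bool = False                    # mid-period service peak option

    # vegetation / soil
    # 30 m pixels of a humid tropical island carry vegetation even in
    # built-up blocks; open water sits lowest
    ndvi_by_class: dict[int, float] = field(default_factory=lambda: {
        FOREST: 0.82, GRASSLAND: 0.74, ARABLE: 0.68,
        BARELAND: 0.50, BUILTUP: 0.45, WATER: 0.15,
    })
    ndvi_noise: float = 0.02
    ndvi_response_amp: float = 0.025    # amplitude of the driver-condition term
    soil_noise: float = 1.0             # 0 disables soil-layer noise

    # driver stack
    coarse_factor: int = 50             # driver cell = coarse_factor x base cell
    driver_effect_weights: dict[str, float] = field(default_factory=_default_weights)
    aet_coefficient: float = 0.55       # AET = min(aet_coefficient * PRE, PET)
    runoff_mean_coefficient: float = 0.35

    def __post_init__(self) -> None:
        total = sum(self.class_targets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_targets must sum to 1, got {total}")
        if self.urban_growth_rate < 0:
            raise ValueError("urban_growth_rate must be >= 0")
        w = self.driver_effect_weights
        if w and max(w, key=w.get) != "PRE":
            raise ValueError("precipitation (PRE) weight must be strictly the maximum")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size)

    @property
    def cat_spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size,
                        nodata=CATEGORICAL_NODATA)

    def rng(self, stream: int, epoch: int | None = None) -> np.random.Generator:
        key = (self.seed, stream) if epoch is None else (self.seed, stream, epoch)
        return np.random.default_rng(np.random.SeedSequence(key))


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Spatially correlated unit-variance noise (Gaussian-smoothed white noise)."""
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return white
    sm = ndimage.gaussian_filter(white, sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _radial_distance(shape: tuple[int, int]) -> np.ndarray:
    """Distance (cells) of each cell centre from the grid centre."""
    r = np.arange(shape[0])[:, None] - (shape[0] - 1) / 2
    c = np.arange(shape[1])[None, :] - (shape[1] - 1) / 2
    return np.hypot(r, c)


def island_mask(scenario: IslandScenario) -> np.ndarray:
    """Boolean land mask: a disk of ``island_radius_frac`` of the short side."""
    shape = (scenario.n_rows, scenario.n_cols)
    r = _radial_distance(shape)
    return r <= scenario.island_radius_frac * min(shape)


def distance_to_coast(scenario: IslandScenario) -> np.ndarray:
    """Distance (m) from each land cell centre to the nearest sea cell."""
    land = island_mask(scenario)
    return ndimage.distance_transform_edt(land) * scenario.cell_size


def make_dem(scenario: IslandScenario) -> Raster:
    """Radially decreasing cone DEM plus smoothed correlated noise; sea is nodata.

    With the noise amplitude at 0 the elevation over land is a pure cone,
    strictly non-increasing with distance from the island centre and zero
    at the coast.
    """
    shape = (scenario.n_rows, scenario.n_cols)
    r = _radial_distance(shape)
    r_coast = scenario.island_radius_frac * min(shape)
    cone = scenario.peak_elevation_m * np.clip(1.0 - r / r_coast, 0.0, None)
    noise = np.zeros(shape)
    if scenario.dem_noise_amp_m > 0:
        rng = scenario.rng(_S_DEM)
        noise = scenario.dem_noise_amp_m * _smooth_noise(
            rng, shape, scenario.noise_sigma_cells)
    elev = np.clip(cone + noise, 0.0, None)
    spec = scenario.spec
    elev[~island_mask(scenario)] = spec.nodata
    return Raster(spec, elev, units="m")


# ---------------------------------------------------------------------------
# land use
# ---------------------------------------------------------------------------

def reserve_mask(scenario: IslandScenario) -> np.ndarray:
    """Integer mask of the interior reserve polygons (0 = outside, 1..k)."""
    shape = (scenario.n_rows, scenario.n_cols)
    out = np.zeros(shape, dtype=np.int64)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    ref = min(shape)
    for i, (rf, cf, rad) in enumerate(scenario.reserves, start=1):
        d = np.hypot(rows - rf * shape[0], cols - cf * shape[1])
        out[d <= rad * ref] = i
    return out


def make_landuse_series(scenario: IslandScenario, dem: Raster
                        ) -> list[CategoricalRaster]:
    """Land-use map per epoch: elevation-structured mosaic + coastal urban growth.

    Epoch-1 class proportions match ``class_targets`` to within rounding
    (forest on the high interior, water and built-up on the low coast).
    Built-up then grows each epoch by converting the most suitable coastal
    arable/forest cells (suitability = -elevation - distance to existing
    built-up), never touching the interior reserves, so its area is
    non-decreasing and every other dynamic is off.
    """
    shape = (scenario.n_rows, scenario.n_cols)
    rng = scenario.rng(_S_LANDUSE)
    land = island_mask(scenario)
    land_idx = np.flatnonzero(land)
    n = len(land_idx)
    elev = np.where(land, dem.values, 0.0)
    d_coast = distance_to_coast(scenario)
    reserves = reserve_mask(scenario) > 0

    counts = {c: int(round(f * n)) for c, f in scenario.class_targets.items()}
    counts[ARABLE] += n - sum(counts.values())  # absorb rounding in the largest flat class
    if min(counts.values()) < 0:
        raise ValueError("class targets infeasible for this grid size")

    # patchiness field: elevation plus correlated noise
    score = (elev + 30.0 * _smooth_noise(rng, shape, scenario.noise_sigma_cells)).ravel()
    order = land_idx[np.argsort(score[land_idx], kind="stable")]
    codes = np.full(shape[0] * shape[1], -1, dtype=np.int64)
    codes[order[:counts[WATER]]] = WATER                  # lowest: coastal water
    codes[order[n - counts[FOREST]:]] = FOREST            # highest: interior forest

    remaining = np.flatnonzero(codes == -1)
    remaining = remaining[land.ravel()[remaining]]
    suit = (-elev / max(scenario.peak_elevation_m, 1.0)
            - d_coast / scenario.coastal_band_m
            + 0.05 * _smooth_noise(rng, shape, 3.0)).ravel()
    rem_sorted = remaining[np.argsort(-suit[remaining], kind="stable")]
    codes[rem_sorted[:counts[BUILTUP]]] = BUILTUP

    for cls, noise_sigma in ((BARELAND, 2.0), (GRASSLAND, 4.0)):
        remaining = np.flatnonzero(codes == -1)
        remaining = remaining[land.ravel()[remaining]]
        f = _smooth_noise(rng, shape, noise_sigma).ravel()
        rem_sorted = remaining[np.argsort(-f[remaining], kind="stable")]
        codes[rem_sorted[:counts[cls]]] = cls
    codes[(codes == -1) & land.ravel()] = ARABLE
    codes[codes == -1] = CATEGORICAL_NODATA               # sea
    codes = codes.reshape(shape)
    codes[reserves & land] = FOREST  # reserves are forested and static

    legend = dict(LANDUSE_LEGEND)
    series = [CategoricalRaster(scenario.cat_spec, codes.copy(), legend)]
    n_new = int(round(scenario.urban_growth_rate * n))
    for _ in scenario.years[1:]:
        codes = codes.copy()
        if n_new > 0:
            built = codes == BUILTUP
            d_built = ndimage.distance_transform_edt(~built) * scenario.cell_size
            eligible = (
                np.isin(codes, (ARABLE, FOREST))
                & (d_coast <= scenario.coastal_band_m)
                & ~reserves
            )
            s = -elev / max(scenario.peak_elevation_m, 1.0) - d_built / scenario.coastal_band_m
            flat = np.flatnonzero(eligible)
            take = flat[np.argsort(-s.ravel()[flat], kind="stable")][:n_new]
            codes.ravel()[take] = BUILTUP
        series.append(CategoricalRaster(scenario.cat_spec, codes, legend))
    return series


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

@dataclass
class ClimateEpoch:
    """Monthly climate stacks for one epoch (arrays are (12, n_rows, n_cols))."""

    year: int
    spec: GridSpec
    precip_monthly: np.ndarray   # mm per month
    tmin_monthly: np.ndarray     # degC
    tmax_monthly: np.ndarray     # degC
    srad_monthly: np.ndarray     # MJ m-2 day-1

    @property
    def precip_annual(self) -> Raster:
        # the annual layer IS the sum of the monthly layers (exact conservation)
        return Raster(self.spec, self.precip_monthly.sum(axis=0), units="mm yr-1")

    @property
    def tmean_annual(self) -> Raster:
        tm = 0.5 * (self.tmin_monthly + self.tmax_monthly)
        return Raster(self.spec, tm.mean(axis=0), units="degC")

    @property
    def srad_annual(self) -> Raster:
        total = (self.srad_monthly * _DAYS[:, None, None]).sum(axis=0)
        return Raster(self.spec, total, units="MJ m-2 yr-1")


def make_climate_series(scenario: IslandScenario, dem: Raster
                        ) -> list[ClimateEpoch]:
    """Monthly precipitation, Tmin/Tmax and radiation per epoch.

    Precipitation is orographic (wetter interior) around a coastal mean in
    the 1000-2000 mm band; temperature lapses with elevation from the
    coastal mean; monthly layers follow fixed monsoon weights so the
    12-month sum is the annual total by construction.
    """
    shape = (scenario.n_rows, scenario.n_cols)
    elev = np.where(dem.mask, dem.values, 0.0)   # sea level over the sea
    # The rainfall anomaly pattern is mesoscale: generated on the coarse
    # driver grid and interpolated down, persistent across epochs.  The
    # coarse-resolution PRE driver therefore observes it almost losslessly,
    # which is what makes precipitation a recoverable dominant driver.
    srng = scenario.rng(_S_CLIMATE)
    cspec = _coarse_spec(scenario)
    coarse_noise = Raster(cspec, _smooth_noise(srng, cspec.shape, 1.0), "1")
    static_anom = (scenario.precip_noise_amp_mm
                   * align(coarse_noise, scenario.spec, kind="continuous").values)
    out = []
    for k, year in enumerate(scenario.years):
        rng = scenario.rng(_S_CLIMATE, k)
        p_mult = 1.0 + scenario.precip_epoch_cv * float(rng.standard_normal())
        t_off = 0.2 * float(rng.standard_normal())
        if scenario.bump_1995 and year == 1995:
            p_mult += 0.08
        p_annual = (
            scenario.coastal_precip_mm
            + scenario.precip_orographic_mm_per_m * elev
            + static_anom
            + 20.0 * _smooth_noise(rng, shape, scenario.noise_sigma_cells)
        ) * p_mult
        p_annual = np.clip(p_annual, 50.0, None)
        precip_m = p_annual[None, :, :] * _MONTH_P_W[:, None, None]

        tmean = scenario.coastal_tmean_c - scenario.lapse_c_per_m * elev + t_off
        tmean_m = tmean[None, :, :] + _MONTH_T_OFF[:, None, None]
        half = scenario.diurnal_range_c / 2.0
        tmin_m = tmean_m - half
        tmax_m = tmean_m + half

        cloud = 0.5 * _smooth_noise(rng, shape, scenario.noise_sigma_cells)
        srad_m = _MONTH_SRAD[:, None, None] + cloud[None, :, :]
        out.append(ClimateEpoch(year, scenario.spec, precip_m, tmin_m, tmax_m,
                                np.clip(srad_m, 1.0, None)))
    return out


# ---------------------------------------------------------------------------
# driver stack (coarse) and vegetation condition
# ---------------------------------------------------------------------------

def _block_mean(a: np.ndarray, f: int) -> np.ndarray:
    nr, nc = a.shape[0] // f, a.shape[1] // f
    return a[: nr * f, : nc * f].reshape(nr, f, nc, f).mean(axis=(1, 3))


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def _coarse_spec(scenario: IslandScenario) -> GridSpec:
    f = scenario.coarse_factor
    return GridSpec(scenario.n_rows // f, scenario.n_cols // f,
                    scenario.cell_size * f)


def _epoch_mean(fields: list[np.ndarray]) -> np.ndarray:
    return np.mean(np.stack(fields), axis=0)


def _base_driver_fields(scenario: IslandScenario,
                        climate: list[ClimateEpoch],
                        dem: Raster) -> dict[str, Raster]:
    """The 11 non-NDVI driver layers at the coarse driver resolution.

    Structural parts derive from the epoch-mean climate; each driver also
    carries its own independent coarse-scale noise so that its effect on
    the vegetation condition is statistically identifiable.  The stack's
    internal identities hold exactly: DEF = PET - AET, AET <= PET,
    RO <= PRE.
    """
    from .services import hargreaves_pet  # services has no dependency on synth

    f = scenario.coarse_factor
    cspec = _coarse_spec(scenario)
    rng = scenario.rng(_S_DRIVERS)
    shape = cspec.shape

    def noise(amp: float, sigma: float = 1.0) -> np.ndarray:
        return amp * _smooth_noise(rng, shape, sigma)

    pre = _block_mean(_epoch_mean([c.precip_annual.values for c in climate]), f)
    tmn_m = _block_mean_stack(_epoch_mean([c.tmin_monthly for c in climate]), f)
    tmx_m = _block_mean_stack(_epoch_mean([c.tmax_monthly for c in climate]), f)
    srad = _block_mean(_epoch_mean([c.srad_annual.values for c in climate]), f)

    tmn = Raster(cspec, tmn_m.mean(axis=0) + noise(0.4), units="degC")
    tmx = Raster(cspec, tmx_m.mean(axis=0) + noise(0.4), units="degC")
    pet = hargreaves_pet(
        [Raster(cspec, tmn_m[m], "degC") for m in range(12)],
        [Raster(cspec, tmx_m[m], "degC") for m in range(12)],
        latitude=19.0,
    )
    pre_r = Raster(cspec, pre + noise(5.0), units="mm yr-1")
    # AET and RO follow precipitation but with their own retrieval noise,
    # so none of the water-balance drivers is a linear copy of PRE
    aet_coeff = np.clip(scenario.aet_coefficient * (1.0 + noise(0.20)), 0.05, 1.0)
    aet = Raster(cspec, np.minimum(aet_coeff * pre_r.values, pet.values),
                 units="mm yr-1")
    deficit = Raster(cspec, pet.values - aet.values, units="mm yr-1")
    ro_coeff = np.clip(scenario.runoff_mean_coefficient + noise(0.15), 0.02, 0.95)
    ro = Raster(cspec, ro_coeff * pre_r.values, units="mm yr-1")
    soil = Raster(cspec, np.clip(
        120.0 + 0.08 * (pre_r.values - aet.values - 800.0) + noise(30.0),
        1.0, None), units="mm")
    vpd = Raster(cspec, np.clip(
        0.9 + 0.08 * (tmx.values - tmx.values.mean()) + noise(0.15),
        0.05, None), units="kPa")
    vs = Raster(cspec, np.clip(3.0 + noise(0.6), 0.1, None), units="m s-1")
    srad_r = Raster(cspec, srad + noise(50.0), units="MJ m-2 yr-1")
    return {
        "AET": aet, "DEF": deficit, "PET": pet, "RO": ro, "SOIL": soil,
        "SRAD": srad_r, "TMN": tmn, "TMX": tmx, "VPD": vpd, "VS": vs,
        "PRE": pre_r,
    }


def _block_mean_stack(a: np.ndarray, f: int) -> np.ndarray:
    return np.stack([_block_mean(a[m], f) for m in range(a.shape[0])])


def vegetation_condition(scenario: IslandScenario,
                         climate: list[ClimateEpoch],
                         dem: Raster) -> np.ndarray:
    """Weighted mix of standardized driver fields, aligned to the base grid.

    Weights come from ``driver_effect_weights`` (precipitation strictly the
    maximum); the result is standardized and clipped to +-2 so a small
    amplitude keeps the class-wise NDVI ordering intact.
    """
    fields = _base_driver_fields(scenario, climate, dem)
    mix = np.zeros(scenario.spec.shape)
    for name, w in scenario.driver_effect_weights.items():
        if name == "NDVI" or name not in fields:
            continue
        coarse = fields[name]
        fine = align(coarse, scenario.spec, kind="continuous")
        mix += w * _zscore(fine.values)
    return np.clip(_zscore(mix), -2.0, 2.0)


# ---------------------------------------------------------------------------
# soil and NDVI
# ---------------------------------------------------------------------------

@dataclass
class SoilLayers:
    """Static soil physical layers (one map each, epoch-invariant)."""

    bulk_density: Raster     # g cm-3
    coarse_fraction: Raster  # % of >2 mm particles
    organic_carbon: Raster   # %
    sand: Raster             # %
    silt: Raster             # %
    clay: Raster             # %


def make_soil_and_ndvi(scenario: IslandScenario,
                       landuse: list[CategoricalRaster],
                       climate: list[ClimateEpoch],
                       dem: Raster) -> tuple[SoilLayers, list[Raster]]:
    """Soil physical layers and class-conditioned NDVI per epoch.

    NDVI = class base value + driver-condition term + interannual noise;
    at zero noise and zero condition amplitude, every built-up cell sits
    strictly below every forest cell.  Soil layers stay inside physically
    plausible bands (BD in [0.9, 1.6] g cm-3, coarse fraction in [0, 60] %).
    """
    shape = (scenario.n_rows, scenario.n_cols)
    rng = scenario.rng(_S_SOIL)
    elev = np.where(dem.mask, dem.values, 0.0)
    amp = scenario.soil_noise
    bd = np.clip(1.25 + 0.10 * amp * _smooth_noise(rng, shape, 6.0), 0.9, 1.6)
    # stonier soils upslope; the whole layer scales with the noise switch
    coarse = np.clip(
        amp * (5.0 + 25.0 * elev / max(scenario.peak_elevation_m, 1.0)
               + 5.0 * _smooth_noise(rng, shape, 6.0)), 0.0, 60.0)
    organic = np.clip(1.8 + 0.4 * amp * _smooth_noise(rng, shape, 6.0), 0.3, 5.0)
    sand = np.clip(40.0 + 6.0 * amp * _smooth_noise(rng, shape, 6.0), 10.0, 80.0)
    clay = np.clip(25.0 + 5.0 * amp * _smooth_noise(rng, shape, 6.0), 5.0, 60.0)
    silt = np.clip(100.0 - sand - clay, 5.0, None)
    spec = scenario.spec
    soils = SoilLayers(
        Raster(spec, bd, "g cm-3"), Raster(spec, coarse, "%"),
        Raster(spec, organic, "%"), Raster(spec, sand, "%"),
        Raster(spec, silt, "%"), Raster(spec, clay, "%"),
    )

    condition = (vegetation_condition(scenario, climate, dem)
                 if scenario.ndvi_response_amp > 0 else np.zeros(shape))
    ndvi_series = []
    for k, lu in enumerate(landuse):
        nrng = scenario.rng(_S_NDVI, k)
        epoch_off = 0.01 * float(nrng.standard_normal())
        if scenario.bump_1995 and scenario.years[k] == 1995:
            epoch_off += 0.02
        base = np.zeros(shape)
        for cls, v in scenario.ndvi_by_class.items():
            base[lu.codes == cls] = v
        ndvi = (base
                + scenario.ndvi_response_amp * condition
                + scenario.ndvi_noise * _smooth_noise(nrng, shape, 3.0)
                + epoch_off)
        ndvi_series.append(Raster(spec, np.clip(ndvi, -0.1, 0.98), units="1"))
    return soils, ndvi_series


def make_driver_stack(scenario: IslandScenario,
                      climate: list[ClimateEpoch],
                      dem: Raster,
                      ndvi_series: list[Raster] | None = None
                      ) -> dict[str, Raster]:
    """The 12 driver layers at the coarse driver resolution.

    NDVI is the epoch-mean NDVI aggregated to the coarse grid; if the NDVI
    series is not supplied it is generated from the scenario.  Use
    :func:`ecoisland.grid.align` to bring the stack onto the base grid.
    """
    fields = _base_driver_fields(scenario, climate, dem)
    if ndvi_series is None:
        dummy_lu = make_landuse_series(scenario, dem)
        _, ndvi_series = make_soil_and_ndvi(scenario, dummy_lu, climate, dem)
    f = scenario.coarse_factor
    cspec = _coarse_spec(scenario)
    ndvi_mean = _epoch_mean([r.values for r in ndvi_series])
    nrng = scenario.rng(_S_DRIVERS, 99)   # NDVI compositing noise
    fields["NDVI"] = Raster(
        cspec,
        _block_mean(ndvi_mean, f) + 0.02 * _smooth_noise(nrng, cspec.shape, 1.0),
        units="1")
    return {name: fields[name] for name in DRIVER_NAMES}


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class IslandData:
    """Everything one scenario generates, in memory."""

    scenario: IslandScenario
    dem: Raster
    landuse: list[CategoricalRaster]
    climate: list[ClimateEpoch]
    soil: SoilLayers
    ndvi: list[Raster]
    drivers: dict[str, Raster]          # coarse resolution
    reserve_zones: np.ndarray           # 0 outside, 1..k per reserve

    @property
    def years(self) -> Sequence[int]:
        return self.scenario.years

    def urban_mask(self) -> np.ndarray:
        """Built-up extent at the final epoch (the human-disturbance zone)."""
        return self.landuse[-1].codes == BUILTUP


def simulate(scenario: IslandScenario) -> IslandData:
    """Generate the full island dataset for one scenario (deterministic)."""
    dem = make_dem(scenario)
    landuse = make_landuse_series(scenario, dem)
    climate = make_climate_series(scenario, dem)
    soil, ndvi = make_soil_and_ndvi(scenario, landuse, climate, dem)
    drivers = make_driver_stack(scenario, climate, dem, ndvi)
    return IslandData(scenario, dem, landuse, climate, soil, ndvi, drivers,
                      reserve_mask(scenario))
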