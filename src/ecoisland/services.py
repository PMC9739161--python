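"""The four ecosystem-service models and their factor sub-models.

Per-cell annual quantities, computed on aligned rasters:

* water retention  ``Q = P - R - ET``            (mm yr-1)
* soil conservation ``A_SE = A_PE - A_AE = R*K*L*S*(1 - C*P)``  (t hm-2 yr-1)
* carbon sequestration ``NEP = NPP - Rh``        (g C m-2 yr-1), with
  ``Rh = 0.592 * Rs^0.714`` and
  ``Rs = 1.55 e^(0.031 T) * P/(P+0.68) * W/(W+2.23)``,
  ``W = 0.58 * BD * H * (1 - delta/100) / 10`` (P in m yr-1, H in cm)
* oxygen release ``Q_O2 = 1.19 * NPP``           (g m-2 yr-1)

The factor sub-models the headline equations rely on (annual runoff via
per-class coefficients, modified-Hargreaves PET, the Wischmeier monthly
erosivity, the EPIC erodibility, RUSLE LS, an NDVI exponential-decay C
factor, and a light-use-efficiency NPP) are standard formulations; every
constant sits in :class:`ServiceParams` so each can be overridden.

Negative water retention and negative NEP are retained, not clipped; the
summary helpers report their area fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import CategoricalRaster, Raster

ARABLE, FOREST, GRASSLAND, WATER, BUILTUP, BARELAND = 1, 2, 3, 4, 5, 6

SERVICE_NAMES = ("water_retention", "soil_conservation",
                 "carbon_sequestration", "oxygen_release")

#: island-total unit per service, as reported
SERVICE_UNITS = {
    "water_retention": "1e9 m3",
    "soil_conservation": "1e9 t",
    "carbon_sequestration": "1e6 t",
    "oxygen_release": "1e6 t",
}

_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 162, 198, 228, 258, 288, 318, 344])


@dataclass
class ServiceParams:
    """All tunable constants of the four service models."""

    # annual runoff coefficient per land-use class (fraction of precipitation)
    runoff_coeffs: dict[int, float] = field(default_factory=lambda: {
        BUILTUP: 0.70, ARABLE: 0.40, FOREST: 0.25,
        GRASSLAND: 0.30, WATER: 0.05, BARELAND: 0.55,
    })
    # crop/cover coefficient scaling PET to ET per class
    et_coefficients: dict[int, float] = field(default_factory=lambda: {
        FOREST: 0.70, GRASSLAND: 0.65, ARABLE: 0.60,
        WATER: 1.00, BUILTUP: 0.30, BARELAND: 0.35,
    })
    # RUSLE support-practice factor per class (water has no erodible surface)
    p_factor: dict[int, float] = field(default_factory=lambda: {
        ARABLE: 0.40, FOREST: 1.00, GRASSLAND: 1.00,
        WATER: 0.00, BUILTUP: 0.20, BARELAND: 1.00,
    })
    latitude_deg: float = 19.0
    # C-factor: C = exp(-c_decay * FVC); FVC linear in NDVI between the bounds
    c_decay: float = 8.0
    ndvi_soil: float = 0.10
    ndvi_veg: float = 0.80
    slope_length_cap_m: float = 100.0
    # CASA-style light-use efficiency; the optimum sits at the prevailing
    # growing-season temperature of a humid tropical island
    eps_max: float = 0.389        # g C MJ-1
    t_opt: float = 23.0           # degC
    # FPAR saturates at moderate NDVI under dense tropical canopy
    fpar_max: float = 0.95
    ndvi_min: float = 0.10
    ndvi_max: float = 0.65
    # carbon sub-model
    soil_thickness_cm: float = 20.0
    o2_coefficient: float = 1.19
    # moisture scalar: AET = min(aet_coefficient * P, PET)
    aet_coefficient: float = 0.55


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _same_spec(*rasters: Raster | CategoricalRaster) -> None:
    shapes = {r.spec.shape for r in rasters}
    if len(shapes) > 1:
        raise ValueError(f"rasters are not aligned: shapes {shapes}")


def _class_lookup(landuse: CategoricalRaster, table: dict[int, float],
                  what: str) -> np.ndarray:
    present = set(landuse.class_counts())
    missing = present - set(table)
    if missing:
        raise KeyError(f"classes {sorted(missing)} missing from the {what} table")
    out = np.zeros(landuse.spec.shape)
    for cls, v in table.items():
        out[landuse.codes == cls] = v
    return out


# ---------------------------------------------------------------------------
# water retention
# ---------------------------------------------------------------------------

def water_retention(precip: Raster, runoff: Raster, et: Raster) -> Raster:
    """Water-balance residual Q = P - R - ET (mm yr-1), negatives retained."""
    _same_spec(precip, runoff, et)
    q = precip.values - runoff.values - et.values
    valid = precip.mask & runoff.mask & et.mask
    out = np.where(valid, q, precip.spec.nodata)
    return Raster(precip.spec, out, units="mm yr-1")


def runoff_from_coefficients(precip: Raster, landuse: CategoricalRaster,
                             coeffs: dict[int, float]) -> Raster:
    """Annual runoff R = coeff(class) * P with per-class coefficients in [0,1]."""
    _same_spec(precip, landuse)
    for cls, c in coeffs.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"runoff coefficient for class {cls} outside [0,1]")
    c = _class_lookup(landuse, coeffs, "runoff-coefficient")
    return Raster(precip.spec, c * precip.values, units="mm yr-1")


def negative_fraction(layer: Raster) -> float:
    """Fraction of valid cells with a negative value (imbalance diagnostic)."""
    m = layer.mask
    return float((layer.values[m] < 0).mean()) if m.any() else 0.0


# ---------------------------------------------------------------------------
# potential evapotranspiration (modified Hargreaves)
# ---------------------------------------------------------------------------

def extraterrestrial_radiation(latitude_deg: float,
                               doy: np.ndarray | int) -> np.ndarray:
    """Daily top-of-atmosphere radiation Ra (MJ m-2 day-1), solar-geometry closed form."""
    phi = np.deg2rad(latitude_deg)
    j = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    gsc = 0.0820  # MJ m-2 min-1
    return (24 * 60 / np.pi) * gsc * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )


def hargreaves_pet(tmin_monthly: Sequence[Raster], tmax_monthly: Sequence[Raster],
                   latitude: float) -> Raster:
    """Annual PET (mm yr-1) from 12 monthly Tmin/Tmax pairs.

    Monthly PET = 0.0023 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin), with Ra
    converted from MJ m-2 day-1 to its evaporation equivalent (x 0.408
    mm day-1), times the days of the month; summed over months.
    """
    if len(tmin_monthly) != 12 or len(tmax_monthly) != 12:
        raise ValueError("need 12 monthly Tmin/Tmax rasters")
    _same_spec(*tmin_monthly, *tmax_monthly)
    ra = 0.408 * extraterrestrial_radiation(latitude, _MID_MONTH_DOY)  # mm day-1
    total = np.zeros(tmin_monthly[0].spec.shape)
    for m in range(12):
        tn, tx = tmin_monthly[m].values, tmax_monthly[m].values
        if np.any(tx < tn):
            raise ValueError(f"Tmax < Tmin in month {m + 1}")
        tmean = 0.5 * (tn + tx)
        total += 0.0023 * ra[m] * (tmean + 17.8) * np.sqrt(tx - tn) * _DAYS[m]
    return Raster(tmin_monthly[0].spec, np.clip(total, 0.0, None), units="mm yr-1")


# ---------------------------------------------------------------------------
# RUSLE factors
# ---------------------------------------------------------------------------

@dataclass
class RusleFactors:
    """The six factor layers of A = R*K*L*S*C*P, all on one grid."""

    r: Raster  # rainfall erosivity, MJ mm ha-1 h-1 yr-1
    k: Raster  # soil erodibility, t ha h ha-1 MJ-1 mm-1
    l: Raster  # slope length (dimensionless)
    s: Raster  # slope steepness (dimensionless)
    c: Raster  # cover (0..1)
    p: Raster  # support practice (0..1)


def rainfall_erosivity(precip_monthly: np.ndarray, spec) -> Raster:
    """Wischmeier monthly erosivity R = sum_m 1.735*10^(1.5*log10(pm^2/P)-0.8188)."""
    p = np.asarray(precip_monthly, dtype=float)
    if p.shape[0] != 12:
        raise ValueError("need a 12-month precipitation stack")
    annual = p.sum(axis=0)
    safe = np.clip(annual, 1e-6, None)
    r = np.zeros(annual.shape)
    for m in range(12):
        ratio = np.clip(p[m] ** 2 / safe, 1e-12, None)
        r += 1.735 * 10.0 ** (1.5 * np.log10(ratio) - 0.8188)
    return Raster(spec, r, units="MJ mm ha-1 h-1 yr-1")


def soil_erodibility(sand: Raster, silt: Raster, clay: Raster,
                     organic_carbon: Raster) -> Raster:
    """EPIC erodibility from texture percentages and organic carbon %, in SI units."""
    _same_spec(sand, silt, clay, organic_carbon)
    san, sil, cla = sand.values, silt.values, clay.values
    oc = organic_carbon.values
    sn1 = 1.0 - san / 100.0
    k = (
        (0.2 + 0.3 * np.exp(-0.0256 * san * (1.0 - sil / 100.0)))
        * (sil / np.clip(cla + sil, 1e-6, None)) ** 0.3
        * (1.0 - 0.25 * oc / (oc + np.exp(3.72 - 2.95 * oc)))
        * (1.0 - 0.7 * sn1 / (sn1 + np.exp(-5.51 + 22.9 * sn1)))
    )
    return Raster(sand.spec, 0.1317 * k, units="t ha h ha-1 MJ-1 mm-1")


def slope_from_dem(dem: Raster) -> np.ndarray:
    """Slope angle theta (radians) from central differences."""
    gy, gx = np.gradient(dem.values, dem.spec.cell_size)
    return np.arctan(np.hypot(gx, gy))


def flow_path_length(dem: Raster, cap_m: float = 300.0) -> np.ndarray:
    """D8 steepest-descent flow-path length (m), capped.

    Cells with no upslope contributor keep the one-cell baseline
    (lambda = cell size); each cell passes its accumulated path length to
    its steepest-descent neighbour.
    """
    z = dem.values
    n_rows, n_cols = z.shape
    cell = dem.spec.cell_size
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    # steepest-descent D8 target of every cell, vectorized over directions
    best_drop = np.zeros(z.shape)
    target = np.full(z.shape, -1, dtype=np.int64)
    target_dist = np.zeros(z.shape)
    flat_idx = np.arange(z.size).reshape(z.shape)
    for dr, dc in offsets:
        d = cell * float(np.hypot(dr, dc))
        drop = np.full(z.shape, -np.inf)
        src = (slice(max(0, -dr), n_rows - max(0, dr)),
               slice(max(0, -dc), n_cols - max(0, dc)))
        dst = (slice(max(0, dr), n_rows + min(0, dr)),
               slice(max(0, dc), n_cols + min(0, dc)))
        drop[src] = (z[src] - z[dst]) / d
        better = drop > best_drop
        best_drop[better] = drop[better]
        tgt = np.full(z.shape, -1, dtype=np.int64)
        tgt[src] = flat_idx[dst]
        target[better] = tgt[better]
        target_dist[better] = d

    lam = np.full(z.size, cell)
    order = np.argsort(z, axis=None, kind="stable")[::-1]  # high to low
    tflat, dflat = target.ravel(), target_dist.ravel()
    for i in order:
        t = tflat[i]
        if t >= 0:
            cand = lam[i] + dflat[i]
            if cand > lam[t]:
                lam[t] = min(cand, cap_m)
    return np.minimum(lam.reshape(z.shape), cap_m)


def ls_factors(dem: Raster, cap_m: float = 300.0) -> tuple[Raster, Raster]:
    """RUSLE slope-length L = (lambda/22.13)^m and steepness S (two segments).

    S = 10.8 sin(theta) + 0.03 for slope < 9 %, else 16.8 sin(theta) - 0.5;
    the exponent m = beta/(1+beta) with beta = (sin/0.0896)/(3 sin^0.8 + 0.56),
    so a flat DEM yields L = 1 and S at its 0.03 floor.
    """
    theta = slope_from_dem(dem)
    sin_t = np.sin(theta)
    s = np.where(np.tan(theta) < 0.09, 10.8 * sin_t + 0.03, 16.8 * sin_t - 0.5)
    beta = (sin_t / 0.0896) / (3.0 * sin_t**0.8 + 0.56)
    m = beta / (1.0 + beta)
    lam = flow_path_length(dem, cap_m)
    l = (lam / 22.13) ** m
    return (Raster(dem.spec, l, units="1"), Raster(dem.spec, s, units="1"))


def cover_factor(ndvi: Raster, ndvi_soil: float = 0.10, ndvi_veg: float = 0.80,
                 decay: float = 8.0) -> Raster:
    """C factor: 1 on bare soil, exponential decay in fractional cover.

    FVC = (NDVI - NDVI_soil)/(NDVI_veg - NDVI_soil) clipped to [0,1];
    C = exp(-decay * FVC), so full cover sits at the exp(-decay) floor.
    """
    fvc = np.clip((ndvi.values - ndvi_soil) / (ndvi_veg - ndvi_soil), 0.0, 1.0)
    return Raster(ndvi.spec, np.exp(-decay * fvc), units="1")


def practice_factor(landuse: CategoricalRaster, table: dict[int, float]) -> Raster:
    for cls, v in table.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"P factor for class {cls} outside [0,1]")
    p = _class_lookup(landuse, table, "practice-factor")
    return Raster(landuse.spec, p, units="1")


def rusle_factors(precip_monthly: np.ndarray, sand: Raster, silt: Raster,
                  clay: Raster, organic_carbon: Raster, dem: Raster,
                  ndvi: Raster, landuse: CategoricalRaster,
                  params: ServiceParams | None = None) -> RusleFactors:
    """Assemble all six RUSLE factor layers from the primary inputs."""
    params = params or ServiceParams()
    _same_spec(sand, dem, ndvi, landuse)
    l, s = ls_factors(dem, params.slope_length_cap_m)
    return RusleFactors(
        r=rainfall_erosivity(precip_monthly, dem.spec),
        k=soil_erodibility(sand, silt, clay, organic_carbon),
        l=l,
        s=s,
        c=cover_factor(ndvi, params.ndvi_soil, params.ndvi_veg, params.c_decay),
        p=practice_factor(landuse, params.p_factor),
    )


def soil_loss_actual(f: RusleFactors) -> Raster:
    """Actual erosion A_AE = R*K*L*S*C*P (t hm-2 yr-1)."""
    _same_spec(f.r, f.k, f.l, f.s, f.c, f.p)
    a = f.r.values * f.k.values * f.l.values * f.s.values * f.c.values * f.p.values
    return Raster(f.r.spec, a, units="t hm-2 yr-1")


def soil_loss_potential(f: RusleFactors) -> Raster:
    """Potential (bare, unmanaged) erosion A_PE = R*K*L*S (t hm-2 yr-1)."""
    _same_spec(f.r, f.k, f.l, f.s)
    return Raster(f.r.spec, f.r.values * f.k.values * f.l.values * f.s.values,
                  units="t hm-2 yr-1")


def soil_conservation(f: RusleFactors) -> Raster:
    """A_SE = A_PE - A_AE = R*K*L*S*(1 - C*P) >= 0 since C, P <= 1."""
    pot = soil_loss_potential(f)
    a = pot.values * (1.0 - f.c.values * f.p.values)
    return Raster(f.r.spec, a, units="t hm-2 yr-1")


# ---------------------------------------------------------------------------
# carbon and oxygen
# ---------------------------------------------------------------------------

def casa_npp(ndvi: Raster, srad_annual: Raster, tmean: Raster,
             water_scalar: Raster | np.ndarray,
             params: ServiceParams | None = None) -> Raster:
    """Light-use-efficiency NPP (g C m-2 yr-1).

    NPP = APAR * eps; APAR = SRAD * FPAR * 0.5 with FPAR linear in NDVI
    between ndvi_min and ndvi_max (clipped to [0, fpar_max]); the
    efficiency eps = eps_max * Ts1 * Ts2 * Weps uses the standard
    temperature scalars around t_opt and the moisture scalar
    Weps = 0.5 + 0.5 * water_scalar, where water_scalar is the
    AET/PET ratio in [0, 1].
    """
    params = params or ServiceParams()
    _same_spec(ndvi, srad_annual, tmean)
    srad = srad_annual.values
    if np.any(srad < 0):
        raise ValueError("negative radiation")
    fpar = np.clip(
        (ndvi.values - params.ndvi_min) / (params.ndvi_max - params.ndvi_min),
        0.0, 1.0) * params.fpar_max
    apar = srad * fpar * 0.5
    topt, t = params.t_opt, tmean.values
    ts1 = 0.8 + 0.02 * topt - 0.0005 * topt**2
    ts2 = 1.1814 / ((1.0 + np.exp(0.2 * (topt - 10.0 - t)))
                    * (1.0 + np.exp(0.3 * (-topt - 10.0 + t))))
    ws = water_scalar.values if isinstance(water_scalar, Raster) else np.asarray(water_scalar)
    weps = 0.5 + 0.5 * np.clip(ws, 0.0, 1.0)
    eps = params.eps_max * ts1 * ts2 * weps
    return Raster(ndvi.spec, apar * eps, units="g C m-2 yr-1")


def soil_respiration(tmean, precip_m, bulk_density, thickness_cm: float = 20.0,
                     coarse_fraction=0.0):
    """Empirical soil respiration Rs (g C m-2 yr-1).

    Rs = 1.55 * e^(0.031 T) * P/(P + 0.68) * W/(W + 2.23), where T is mean
    annual air temperature (degC), P annual precipitation (m yr-1) and
    W = 0.58 * BD * H * (1 - delta/100) / 10 the fine-soil water-capacity
    term (BD g cm-3, H cm, delta the >2 mm coarse fraction in %).
    Accepts scalars or arrays; Rasters pass their value grids.
    """
    def v(x):
        return x.values if isinstance(x, Raster) else np.asarray(x, dtype=float)

    t, p, bd, delta = v(tmean), v(precip_m), v(bulk_density), v(coarse_fraction)
    if np.any(p < 0):
        raise ValueError("negative precipitation")
    if np.any((delta < 0) | (delta > 100)):
        raise ValueError("coarse fraction outside [0, 100] %")
    w = 0.58 * bd * thickness_cm * (1.0 - delta / 100.0) / 10.0
    rs = 1.55 * np.exp(0.031 * t) * p / (p + 0.68) * w / (w + 2.23)
    if isinstance(tmean, Raster):
        return Raster(tmean.spec, rs, units="g C m-2 yr-1")
    return rs


def heterotrophic_respiration(rs):
    """Rh = 0.592 * Rs^0.714 (g C m-2 yr-1)."""
    vals = rs.values if isinstance(rs, Raster) else np.asarray(rs, dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative soil respiration")
    rh = 0.592 * vals**0.714
    if isinstance(rs, Raster):
        return Raster(rs.spec, rh, units="g C m-2 yr-1")
    return rh


def nep(npp: Raster, rh: Raster) -> Raster:
    """Net ecosystem productivity NPP - Rh; negative cells are carbon sources."""
    _same_spec(npp, rh)
    return Raster(npp.spec, npp.values - rh.values, units="g C m-2 yr-1")


def oxygen_release(npp: Raster, coefficient: float = 1.19) -> Raster:
    """Q_O2 = 1.19 * NPP (g m-2 yr-1)."""
    if np.any(npp.values[npp.mask] < 0):
        raise ValueError("NPP must be non-negative")
    return Raster(npp.spec, coefficient * npp.values, units="g m-2 yr-1")


# ---------------------------------------------------------------------------
# island totals
# ---------------------------------------------------------------------------

@dataclass
class ServiceStack:
    """Per-epoch service layers plus island-wide totals in reporting units."""

    service: str
    years: Sequence[int]
    rasters: Sequence[Raster] | None
    totals: list[float]          # in SERVICE_UNITS[service]
    units: str

    @property
    def change(self) -> float:
        """First-to-last epoch change of the island total."""
        return self.totals[-1] - self.totals[0]


def _layer_total(layer: Raster, service: str) -> float:
    """Island total of one layer in the reporting unit of the service."""
    area_m2 = layer.spec.cell_area_m2
    s = float(layer.values[layer.mask].sum())
    if service == "water_retention":
        return s * 1e-3 * area_m2 / 1e9          # mm -> m3, report 1e9 m3
    if service == "soil_conservation":
        return s * (area_m2 / 1e4) / 1e9         # t/ha * ha -> t, report 1e9 t
    if service in ("carbon_sequestration", "oxygen_release"):
        return s * area_m2 * 1e-6 / 1e6          # g/m2 -> t, report 1e6 t
    raise ValueError(f"unknown service {service!r}")


def island_totals(rasters: Sequence[Raster], service: str,
                  years: Sequence[int]) -> ServiceStack:
    """Aggregate per-epoch layers to island-wide physical totals."""
    if len(rasters) != len(years):
        raise ValueError("one raster per epoch required")
    totals = [_layer_total(r, service) for r in rasters]
    return ServiceStack(service, list(years), list(rasters), totals,
                        SERVICE_UNITS[service])


def ingest_totals(service: str, years: Sequence[int],
                  totals: Sequence[float]) -> ServiceStack:
    """Wrap an externally reported island-total series (no rasters)."""
    if len(totals) != len(years):
        raise ValueError("one total per epoch required")
    return ServiceStack(service, list(years), None, [float(t) for t in totals],
                        SERVICE_UNITS.get(service, "1"))
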