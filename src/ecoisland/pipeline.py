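"""End-to-end orchestration: simulate -> granularity -> services -> trends -> drivers.

`run_all` executes the whole chain from one seeded configuration and
writes every tabular product as CSV plus a JSON run manifest; rerunning
with the same configuration reproduces the CSVs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import services as svc
from .drivers import rank_drivers_per_service
from .grid import Raster, align, write_raster
from .landscape import (
    cv_report,
    find_optimal_granularity,
    granularity_series,
    metric_curve,
    select_sensitive,
    tables_to_frame,
)
from .synth import DRIVER_NAMES, IslandData, IslandScenario, simulate
from .trends import area_series, pixel_trend, transition_matrix, zonal_series


@dataclass
class RunConfig:
    """Everything a full run depends on, serializable for the manifest."""

    scenario: IslandScenario = field(default_factory=IslandScenario)
    params: svc.ServiceParams = field(default_factory=svc.ServiceParams)
    granularities: tuple[float, ...] = tuple(range(30, 301, 10))
    cv_threshold: float = 5.0
    granularity_year: int | None = None    # None: pick the max-mean-CV year
    inflection_metric: str = "SPLIT"
    stability_tol: float | None = None
    n_samples: int = 1000
    n_trees: int = 500
    n_repeats: int = 10
    min_spacing: float = 0.0
    write_rasters: bool = False
    stages: tuple[str, ...] = ("simulate", "granularity", "services",
                               "trends", "drivers")

    @property
    def seed(self) -> int:
        return self.scenario.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["years"] = list(self.scenario.years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scen = d.pop("scenario", {})
        if isinstance(scen, dict):
            if "class_targets" in scen:
                scen["class_targets"] = {int(k): v for k, v in scen["class_targets"].items()}
            if "ndvi_by_class" in scen:
                scen["ndvi_by_class"] = {int(k): v for k, v in scen["ndvi_by_class"].items()}
            if "years" in scen:
                scen["years"] = tuple(scen["years"])
            scen = IslandScenario(**scen)
        par = d.pop("params", {})
        if isinstance(par, dict):
            for key in ("runoff_coeffs", "et_coefficients", "p_factor"):
                if key in par:
                    par[key] = {int(k): v for k, v in par[key].items()}
            par = svc.ServiceParams(**par)
        if "granularities" in d:
            d["granularities"] = tuple(d["granularities"])
        return cls(scenario=scen, params=par, **d)


# ---------------------------------------------------------------------------
# services orchestration
# ---------------------------------------------------------------------------

def compute_services(island: IslandData,
                     params: svc.ServiceParams | None = None
                     ) -> dict[str, svc.ServiceStack]:
    """All four service layers for every epoch, plus island totals."""
    params = params or svc.ServiceParams()
    scen = island.scenario
    soils = island.soil
    erodibility = svc.soil_erodibility(soils.sand, soils.silt, soils.clay,
                                       soils.organic_carbon)
    # terrain factors on a sea-level-filled DEM; sea cells are masked below
    dem_filled = Raster(island.dem.spec,
                        np.where(island.dem.mask, island.dem.values, 0.0), "m")
    l_factor, s_factor = svc.ls_factors(dem_filled, params.slope_length_cap_m)

    per_service: dict[str, list[Raster]] = {name: [] for name in svc.SERVICE_NAMES}
    for k, year in enumerate(scen.years):
        clim = island.climate[k]
        lu = island.landuse[k]
        ndvi = island.ndvi[k]
        precip = clim.precip_annual
        spec = precip.spec

        # water balance
        runoff = svc.runoff_from_coefficients(precip, lu, params.runoff_coeffs)
        tmin_r = [Raster(spec, clim.tmin_monthly[m], "degC") for m in range(12)]
        tmax_r = [Raster(spec, clim.tmax_monthly[m], "degC") for m in range(12)]
        pet = svc.hargreaves_pet(tmin_r, tmax_r, params.latitude_deg)
        kc = np.zeros(spec.shape)
        for cls, v in params.et_coefficients.items():
            kc[lu.codes == cls] = v
        et = Raster(spec, kc * pet.values, units="mm yr-1")
        per_service["water_retention"].append(svc.water_retention(precip, runoff, et))

        # RUSLE
        factors = svc.RusleFactors(
            r=svc.rainfall_erosivity(clim.precip_monthly, spec),
            k=erodibility, l=l_factor, s=s_factor,
            c=svc.cover_factor(ndvi, params.ndvi_soil, params.ndvi_veg,
                               params.c_decay),
            p=svc.practice_factor(lu, params.p_factor),
        )
        per_service["soil_conservation"].append(svc.soil_conservation(factors))

        # carbon and oxygen
        tmean = clim.tmean_annual
        aet = np.minimum(params.aet_coefficient * precip.values, pet.values)
        water_scalar = Raster(spec, aet / np.clip(pet.values, 1e-6, None), "1")
        npp = svc.casa_npp(ndvi, clim.srad_annual, tmean, water_scalar, params)
        rs = svc.soil_respiration(tmean, precip.values / 1000.0,
                                  soils.bulk_density.values,
                                  params.soil_thickness_cm,
                                  soils.coarse_fraction.values)
        rh = svc.heterotrophic_respiration(rs)   # Raster (tmean is a Raster)
        nep_layer = svc.nep(npp, rh)
        o2_layer = svc.oxygen_release(npp, params.o2_coefficient)
        # the productivity models describe terrestrial ecosystems; open
        # water is excluded (nodata) from the carbon and oxygen layers
        water = lu.codes == svc.WATER
        nep_layer.values[water] = spec.nodata
        o2_layer.values[water] = spec.nodata
        per_service["carbon_sequestration"].append(nep_layer)
        per_service["oxygen_release"].append(o2_layer)

        # everything outside the land mask (sea) is nodata
        for layers in per_service.values():
            layers[-1].values[~lu.mask] = spec.nodata

    return {name: svc.island_totals(layers, name, scen.years)
            for name, layers in per_service.items()}


def epoch_mean_layer(stack: svc.ServiceStack) -> Raster:
    """Multi-epoch mean service layer (the driver-analysis response).

    A cell is valid only where every epoch is valid; otherwise nodata.
    """
    spec = stack.rasters[0].spec
    vals = np.stack([r.values for r in stack.rasters])
    allvalid = np.stack([r.mask for r in stack.rasters]).all(axis=0)
    mean = np.where(allvalid, vals.mean(axis=0), spec.nodata)
    return Raster(spec, mean, units=stack.rasters[0].units)


def totals_frame(stacks: dict[str, svc.ServiceStack]) -> pd.DataFrame:
    """Years-as-columns totals table with a first-to-last change column."""
    rows = []
    for name, st in stacks.items():
        row = {"service": name, "units": st.units}
        row.update({str(y): t for y, t in zip(st.years, st.totals)})
        row["change"] = st.change
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g")
    return str(path)


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    stages_on = set(config.stages)
    for dependent in ("trends", "drivers"):
        if dependent in stages_on and "services" not in stages_on:
            raise ValueError(f"{dependent} stage requires the services stage")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "stages": {},
        "outputs": [],
    }

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)

        return done

    # 1. simulate
    tick = stage("simulate")
    island = simulate(config.scenario)
    if config.write_rasters:
        rdir = out / "rasters"
        for k, lu in enumerate(island.landuse):
            write_raster(lu, rdir / f"landuse_{island.years[k]}.tif")
        write_raster(island.dem, rdir / "dem.tif")
    manifest["outputs"].append(_write_csv(area_series(island.landuse),
                                          out / "area_series.csv"))
    tick()

    # 2. granularity
    if "granularity" in stages_on:
        _run_granularity(config, island, out, manifest, stage)

    # 3-5. services, trends, drivers
    if "services" in stages_on:
        _run_services_and_downstream(config, island, out, manifest, stage,
                                     stages_on)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_granularity(config, island, out, manifest, stage):
    tick = stage("granularity")
    per_year = {}
    for k, year in enumerate(island.years):
        tables = granularity_series(island.landuse[k], config.granularities)
        per_year[year] = tables
        manifest["outputs"].append(_write_csv(
            tables_to_frame(tables), out / f"metrics_{year}.csv"))
    reports = {y: cv_report(t, config.cv_threshold) for y, t in per_year.items()}
    if config.granularity_year is None:
        year_sel = max(reports, key=lambda y: np.nanmean(
            [v for v in reports[y].cv.values() if np.isfinite(v)]))
    else:
        year_sel = config.granularity_year
    report = reports[year_sel]
    cv_frame = pd.DataFrame(
        {"metric": list(report.cv), "cv_pct": list(report.cv.values()),
         "sensitive": [report.sensitive[m] for m in report.cv]})
    manifest["outputs"].append(_write_csv(cv_frame, out / "cv_report.csv"))
    curve = metric_curve(per_year[year_sel], config.inflection_metric)
    selected = find_optimal_granularity(curve)
    manifest["granularity"] = {
        "year": int(year_sel),
        "sensitive": sorted(select_sensitive(report)),
        "selected_scale_m": selected,
    }
    tick()


def _run_services_and_downstream(config, island, out, manifest, stage,
                                 stages_on):
    tick = stage("services")
    stacks = compute_services(island, config.params)
    manifest["outputs"].append(_write_csv(totals_frame(stacks),
                                          out / "service_totals.csv"))
    tick()

    if "trends" not in stages_on:
        if "drivers" in stages_on:
            _run_drivers(config, island, stacks, out, manifest, stage)
        return

    # 4. trends
    tick = stage("trends")
    tm = transition_matrix(island.landuse[0], island.landuse[-1])
    tm_frame = tm.table.reset_index(names="from_class")
    manifest["outputs"].append(_write_csv(tm_frame, out / "transition_matrix.csv"))
    zrows = []
    urban = island.urban_mask()
    for name, st in stacks.items():
        trend = pixel_trend(st.rasters, config.stability_tol)
        manifest.setdefault("trend_sign_fractions", {})[name] = {
            "increase": float((trend.sign == 1).mean()),
            "decrease": float((trend.sign == -1).mean()),
            "stable": float((trend.sign == 0).mean()),
        }
        zs = zonal_series(st.rasters, urban, "urban_2015")
        zrows.append({"service": name, "zone": zs.zone, "r": zs.r,
                      **{str(y): v for y, v in zip(st.years, zs.values)}})
        for rid in np.unique(island.reserve_zones[island.reserve_zones > 0]):
            rz = zonal_series(st.rasters, island.reserve_zones == rid,
                              f"reserve_{rid}")
            zrows.append({"service": name, "zone": rz.zone, "r": rz.r,
                          **{str(y): v for y, v in zip(st.years, rz.values)}})
    manifest["outputs"].append(_write_csv(pd.DataFrame(zrows),
                                          out / "zonal_series.csv"))
    tick()

    if "drivers" in stages_on:
        _run_drivers(config, island, stacks, out, manifest, stage)


def _run_drivers(config, island, stacks, out, manifest, stage):
    tick = stage("drivers")
    base_spec = island.dem.spec
    aligned = {name: align(island.drivers[name], base_spec, kind="continuous")
               for name in DRIVER_NAMES}
    responses = {name: epoch_mean_layer(st) for name, st in stacks.items()}
    rankings = rank_drivers_per_service(
        aligned, responses, n_samples=config.n_samples, n_trees=config.n_trees,
        n_repeats=config.n_repeats, seed=config.seed,
        min_spacing=config.min_spacing)
    frames = []
    for name, ranking in rankings.items():
        f = ranking.to_frame()
        f.insert(0, "service", name)
        frames.append(f)
    manifest["outputs"].append(_write_csv(pd.concat(frames, ignore_index=True),
                                          out / "driver_rankings.csv"))
    manifest["top_driver"] = {name: r.top for name, r in rankings.items()}
    tick()
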