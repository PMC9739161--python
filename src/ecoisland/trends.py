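"""Land-use change accounting, per-pixel service trends, zonal comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import CategoricalRaster, Raster, zonal_mean


@dataclass
class TransitionMatrix:
    """class x class area cross-tabulation (km2) between two epochs."""

    table: pd.DataFrame            # rows: from-class, cols: to-class, km2
    change_ratio_pct: pd.Series    # (area_b - area_a) / total area * 100 per class

    @property
    def total_km2(self) -> float:
        return float(self.table.to_numpy().sum())

    @property
    def unchanged_fraction(self) -> float:
        return float(np.trace(self.table.to_numpy()) / self.total_km2)

    @property
    def changed_fraction(self) -> float:
        return 1.0 - self.unchanged_fraction


def transition_matrix(lu_a: CategoricalRaster, lu_b: CategoricalRaster
                      ) -> TransitionMatrix:
    """Exhaustive cross-tabulation of cells valid in both epochs."""
    if lu_a.spec.shape != lu_b.spec.shape:
        raise ValueError("epoch maps are on different grids")
    valid = lu_a.mask & lu_b.mask
    classes = sorted(set(lu_a.legend) | set(lu_b.legend))
    idx = {c: i for i, c in enumerate(classes)}
    m = len(classes)
    counts = np.zeros((m, m), dtype=np.int64)
    ia = np.vectorize(idx.get)(lu_a.codes[valid])
    ib = np.vectorize(idx.get)(lu_b.codes[valid])
    np.add.at(counts, (ia, ib), 1)
    km2 = lu_a.spec.cell_area_m2 / 1e6
    names = [lu_a.legend.get(c, str(c)) for c in classes]
    table = pd.DataFrame(counts * km2, index=names, columns=names)
    total = counts.sum() * km2
    ratio = (counts.sum(axis=0) - counts.sum(axis=1)) * km2 / total * 100.0
    return TransitionMatrix(table, pd.Series(ratio, index=names))


def area_series(lu_stack: Sequence[CategoricalRaster]
                ) -> pd.DataFrame:
    """Per-class area (km2) and fraction per epoch; fractions sum to 1."""
    legends = [tuple(sorted(lu.legend.items())) for lu in lu_stack]
    if len(set(legends)) > 1:
        raise ValueError("legend drifts across epochs")
    classes = sorted(lu_stack[0].legend)
    km2 = lu_stack[0].spec.cell_area_m2 / 1e6
    rows = []
    for k, lu in enumerate(lu_stack):
        counts = lu.class_counts()
        total = sum(counts.values())
        for c in classes:
            n = counts.get(c, 0)
            rows.append({
                "epoch": k, "class": c, "name": lu.legend[c],
                "area_km2": n * km2, "fraction": n / total,
            })
    return pd.DataFrame(rows)


@dataclass
class TrendMap:
    """OLS slope per cell against epoch index, with a sign classification."""

    slope: Raster                 # service units per epoch step
    sign: np.ndarray              # +1 increase, -1 decrease, 0 stable
    stability_tol: float


def pixel_trend(stack: Sequence[Raster], stability_tol: float | None = None
                ) -> TrendMap:
    """Per-cell least-squares slope of the service value against epoch index.

    The regressor is the epoch index 0..T-1 (epochs are unevenly spaced in
    calendar years).  |slope| <= tol classifies as stable; the default tol
    is 1 % of the stack-wide interquartile range of the values.
    """
    if len(stack) < 3:
        raise ValueError("need at least 3 epochs for a trend")
    spec = stack[0].spec
    vals = np.stack([r.values for r in stack])          # (T, H, W)
    masks = np.stack([r.mask for r in stack])
    allvalid = masks.all(axis=0)
    t = np.arange(len(stack), dtype=float)
    tc = t - t.mean()
    denom = float((tc**2).sum())
    slope = np.einsum("t,tij->ij", tc, vals) / denom    # centred-x closed form
    slope = np.where(allvalid, slope, spec.nodata)
    if stability_tol is None:
        finite = vals[masks]
        q75, q25 = np.percentile(finite, [75, 25])
        stability_tol = 0.01 * (q75 - q25)
    sign = np.zeros(spec.shape, dtype=np.int8)
    sign[allvalid & (slope > stability_tol)] = 1
    sign[allvalid & (slope < -stability_tol)] = -1
    slope_r = Raster(spec, slope, units=f"{stack[0].units} per epoch")
    return TrendMap(slope_r, sign, float(stability_tol))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either series is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series of length >= 3")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class ZonalSeries:
    """Per-epoch mean service value inside one zone, vs the island series."""

    zone: str
    values: list[float]
    island_values: list[float]
    r: float


def zonal_series(stack: Sequence[Raster], mask: np.ndarray, zone_name: str,
                 island_series: Sequence[float] | None = None) -> ZonalSeries:
    """Zonal mean per epoch plus Pearson r against the island-wide series."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"zone {zone_name!r} is empty")
    values = []
    island = []
    for r in stack:
        zm = zonal_mean(r, mask)
        if 1 not in zm:
            raise ValueError(f"zone {zone_name!r} has no valid cells in an epoch")
        values.append(zm[1])
        island.append(float(r.values[r.mask].mean()))
    if island_series is not None:
        island = [float(v) for v in island_series]
    return ZonalSeries(zone_name, values, island, pearson_r(values, island))
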