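"""Landscape-level pattern indices, grain-sensitivity screen, optimal grain.

Seventeen whole-landscape indices (TA, NP, PD, LPI, ED, LSI, SHAPE_MN,
PAFRAC, CONTAG, PLADJ, IJI, COHESION, DIVISION, SPLIT, SHDI, SHEI, AI) are
computed from first principles on categorical rasters, following the
standard FRAGSTATS landscape-level definitions.  Conventions, fixed here
and relied on by every formula:

* patches are 8-connected components of one class;
* patch perimeter counts cell-edge segments adjacent to a different
  class, to nodata, or to the map boundary (the "no border" convention:
  the landscape boundary is edge);
* cell adjacencies for CONTAG/PLADJ use the double-count method over
  4-neighbour pairs of valid cells; AI uses single-count like
  adjacencies; IJI uses internal class-to-class edge only (no boundary);
* indices undefined on a given map (CONTAG with one class, IJI with
  fewer than three, PAFRAC with fewer than two patches) are reported as
  NaN, never as 0; SHEI is 0 on a one-class map.

The grain (granularity) analysis aggregates the base map to a series of
coarser cell sizes, screens indices by the coefficient of variation of
their response, and locates the first inflection of a response curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import CategoricalRaster, majority_resample

METRIC_NAMES = (
    "TA", "NP", "PD", "LPI", "ED", "LSI", "SHAPE_MN", "PAFRAC", "CONTAG",
    "PLADJ", "IJI", "COHESION", "DIVISION", "SPLIT", "SHDI", "SHEI", "AI",
)

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class MetricTable:
    """All 17 landscape-level indices for one (map, granularity) pair."""

    granularity: float
    metrics: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.metrics[name]


@dataclass
class CVReport:
    """Per-metric coefficient of variation across a granularity series."""

    cv: dict[str, float]
    threshold: float = 5.0

    @property
    def sensitive(self) -> dict[str, bool]:
        return {m: (np.isfinite(v) and v > self.threshold)
                for m, v in self.cv.items()}


@dataclass
class GranularityCurve:
    """One metric's response to grain: (granularity, value) pairs."""

    metric: str
    granularities: Sequence[float]
    values: Sequence[float]


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def label_patches(cmap: CategoricalRaster
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """8-connected per-class patches.

    Returns the patch-id grid (0 = nodata) and a table with one row per
    patch: id, class code, area (m2), perimeter (m).
    """
    codes = cmap.codes
    valid = cmap.mask
    if not valid.any():
        raise ValueError("all-nodata map has no patches")
    labels = np.zeros(codes.shape, dtype=np.int64)
    classes = []
    next_id = 0
    for cls in sorted(np.unique(codes[valid]).tolist()):
        lab, n = ndimage.label(codes == cls, structure=_EIGHT)
        sel = lab > 0
        labels[sel] = lab[sel] + next_id
        classes.extend([cls] * n)
        next_id += n

    cell = cmap.spec.cell_size
    areas_cells = np.bincount(labels.ravel(), minlength=next_id + 1)[1:]
    perim = _perimeter_faces(labels) * cell
    return labels, pd.DataFrame({
        "patch_id": np.arange(1, next_id + 1),
        "class": np.asarray(classes, dtype=np.int64),
        "area_m2": areas_cells * cell * cell,
        "perimeter_m": perim,
    })


def _perimeter_faces(labels: np.ndarray) -> np.ndarray:
    """Per-patch count of exposed cell faces (different label, nodata or boundary)."""
    n = int(labels.max())
    faces = np.zeros(labels.shape, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = padded[1 + dr: padded.shape[0] - 1 + dr,
                    1 + dc: padded.shape[1] - 1 + dc]
        faces += (labels > 0) & (nb != labels)
    return np.bincount(labels.ravel(), weights=faces.ravel(), minlength=n + 1)[1:]


def _adjacency_matrix(cmap: CategoricalRaster) -> tuple[np.ndarray, list[int]]:
    """Double-count 4-neighbour adjacency matrix between valid-cell classes."""
    codes = cmap.codes
    valid = cmap.mask
    classes = sorted(np.unique(codes[valid]).tolist())
    index = {c: i for i, c in enumerate(classes)}
    m = len(classes)
    g = np.zeros((m, m), dtype=np.int64)
    for axis in (0, 1):
        a = codes.take(range(codes.shape[axis] - 1), axis=axis)
        b = codes.take(range(1, codes.shape[axis]), axis=axis)
        va = valid.take(range(codes.shape[axis] - 1), axis=axis)
        vb = valid.take(range(1, codes.shape[axis]), axis=axis)
        ok = va & vb
        ia = np.vectorize(index.get, otypes=[np.int64])(a[ok]) if ok.any() else np.array([], dtype=np.int64)
        ib = np.vectorize(index.get, otypes=[np.int64])(b[ok]) if ok.any() else np.array([], dtype=np.int64)
        np.add.at(g, (ia, ib), 1)
        np.add.at(g, (ib, ia), 1)
    return g, classes


def _max_like_adjacencies(n_cells: int) -> int:
    """Largest possible single-count like-adjacency count for n_cells cells."""
    n = int(math.isqrt(n_cells))
    m = n_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


# ---------------------------------------------------------------------------
# the 17 indices
# ---------------------------------------------------------------------------

def landscape_metrics(cmap: CategoricalRaster) -> MetricTable:
    """All 17 landscape-level indices for one categorical map."""
    labels, patches = label_patches(cmap)
    cell = cmap.spec.cell_size
    cell_area = cell * cell
    valid = cmap.mask
    z = int(valid.sum())                       # number of valid cells
    area_m2 = z * cell_area                    # A
    ta_ha = area_m2 / 1e4

    a = patches["area_m2"].to_numpy()
    p = patches["perimeter_m"].to_numpy()
    n_patches = len(patches)

    # total edge E: internal unlike edges once + outer boundary/nodata edges.
    # sum of patch perimeters counts internal edges twice: E = (sum(p)+B)/2
    # where B is the boundary/nodata edge length; recover B directly.
    boundary = 0
    padded = np.pad(valid, 1, constant_values=False)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = padded[1 + dr: padded.shape[0] - 1 + dr,
                    1 + dc: padded.shape[1] - 1 + dc]
        boundary += int((valid & ~nb).sum())
    boundary_m = boundary * cell
    total_edge = (p.sum() + boundary_m) / 2.0  # m

    g, classes = _adjacency_matrix(cmap)
    m = len(classes)
    counts = np.array([(cmap.codes[valid] == c).sum() for c in classes])
    prop = counts / z

    out: dict[str, float] = {}
    out["TA"] = ta_ha
    out["NP"] = float(n_patches)
    out["PD"] = n_patches / ta_ha * 100.0
    out["LPI"] = float(a.max()) / area_m2 * 100.0
    out["ED"] = total_edge / ta_ha
    out["LSI"] = 0.25 * total_edge / math.sqrt(area_m2)
    out["SHAPE_MN"] = float(np.mean(0.25 * p / np.sqrt(a)))
    out["PAFRAC"] = _pafrac(a, p)
    out["CONTAG"] = _contag(g, prop, m)
    total_adj = g.sum()
    out["PLADJ"] = 100.0 * np.trace(g) / total_adj if total_adj > 0 else float("nan")
    out["IJI"] = _iji(g, m)
    out["COHESION"] = _cohesion(a / cell_area, p / cell, z)
    out["DIVISION"] = 1.0 - float(((a / area_m2) ** 2).sum())
    out["SPLIT"] = area_m2**2 / float((a.astype(float) ** 2).sum())
    shdi = -float(np.sum(prop * np.log(prop)))
    out["SHDI"] = shdi
    out["SHEI"] = shdi / math.log(m) if m > 1 else 0.0
    out["AI"] = _aggregation_index(g, counts, prop)
    return MetricTable(cmap.spec.cell_size, out)


def _pafrac(a: np.ndarray, p: np.ndarray) -> float:
    # 2 / slope of ln(area) regressed on ln(perimeter); needs spread in p
    if len(a) < 2:
        return float("nan")
    x, y = np.log(p), np.log(a)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        return float("nan")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    if slope == 0:
        return float("nan")
    return 2.0 / slope


def _contag(g: np.ndarray, prop: np.ndarray, m: int) -> float:
    if m < 2:
        return float("nan")
    row_sums = g.sum(axis=1)
    acc = 0.0
    for i in range(m):
        if row_sums[i] == 0:
            continue
        for k in range(m):
            q = prop[i] * g[i, k] / row_sums[i]
            if q > 0:
                acc += q * math.log(q)
    return (1.0 + acc / (2.0 * math.log(m))) * 100.0


def _iji(g: np.ndarray, m: int) -> float:
    if m < 3:
        return float("nan")
    # internal class-to-class edge, single count (upper triangle of g/2)
    e = np.triu(g, 1) / 2.0
    total = e.sum()
    if total <= 0:
        return float("nan")
    acc = 0.0
    for i in range(m):
        for k in range(i + 1, m):
            if e[i, k] > 0:
                f = e[i, k] / total
                acc -= f * math.log(f)
    return acc / math.log(0.5 * m * (m - 1)) * 100.0


def _cohesion(a_cells: np.ndarray, p_faces: np.ndarray, z: int) -> float:
    if z <= 1:
        return float("nan")
    num = p_faces.sum()
    den = float(np.sum(p_faces * np.sqrt(a_cells)))
    return (1.0 - num / den) / (1.0 - 1.0 / math.sqrt(z)) * 100.0


def _aggregation_index(g: np.ndarray, counts: np.ndarray,
                       prop: np.ndarray) -> float:
    acc = 0.0
    for i in range(len(counts)):
        max_g = _max_like_adjacencies(int(counts[i]))
        if max_g > 0:
            acc += prop[i] * (g[i, i] / 2.0) / max_g   # single-count like adjacencies
    return acc * 100.0


# ---------------------------------------------------------------------------
# granularity series, CV screen, inflection
# ---------------------------------------------------------------------------

def granularity_series(base: CategoricalRaster,
                       granularities: Sequence[float] | None = None
                       ) -> list[MetricTable]:
    """Metric tables along a grain series (default 30-300 m in 10 m steps)."""
    if granularities is None:
        granularities = tuple(range(30, 301, 10))
    out = []
    for g in granularities:
        coarse = majority_resample(base, float(g))
        table = landscape_metrics(coarse)
        table.granularity = float(g)
        out.append(table)
    return out


def coefficient_of_variation(series: Sequence[float]) -> float:
    """CV % = sample standard deviation / mean * 100; NaN on zero mean."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(x.std(ddof=1) / abs(mean) * 100.0)


def cv_report(tables: Sequence[MetricTable], threshold: float = 5.0) -> CVReport:
    """CV of every metric across the granularity series (NaN-valued levels skipped)."""
    cv: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.asarray([t.metrics[name] for t in tables], dtype=float)
        vals = vals[np.isfinite(vals)]
        cv[name] = coefficient_of_variation(vals) if len(vals) >= 2 else float("nan")
    return CVReport(cv, threshold)


def select_sensitive(report: CVReport) -> set[str]:
    """Metric names whose CV strictly exceeds the threshold (5.0 % -> not sensitive)."""
    return {m for m, flag in report.sensitive.items() if flag}


def find_optimal_granularity(curve: GranularityCurve,
                             rel_tol: float = 0.05) -> float | None:
    """First inflection of a grain-response curve, or None.

    Second differences with magnitude below ``rel_tol`` times the value
    range are treated as zero curvature.  An inflection is the first
    interior point whose significant curvature either follows a flat
    (zero-curvature) stretch or flips the sign of the previous significant
    curvature — so straight lines and constant-curvature series have none.
    """
    g = np.asarray(curve.granularities, dtype=float)
    v = np.asarray(curve.values, dtype=float)
    if len(g) < 4:
        raise ValueError("need at least 4 points to locate an inflection")
    d2 = v[2:] - 2 * v[1:-1] + v[:-2]          # curvature at interior points
    tol = rel_tol * (v.max() - v.min())
    sign = np.where(np.abs(d2) > tol, np.sign(d2), 0.0)
    last_nonzero = 0.0
    for k in range(len(sign)):
        s = sign[k]
        if s != 0.0:
            flat_before = k > 0 and sign[k - 1] == 0.0
            flipped = last_nonzero != 0.0 and s != last_nonzero
            if flat_before or flipped:
                return float(g[k + 1])
            last_nonzero = s
    return None


def metric_curve(tables: Sequence[MetricTable], metric: str) -> GranularityCurve:
    return GranularityCurve(
        metric,
        [t.granularity for t in tables],
        [t.metrics[metric] for t in tables],
    )


def tables_to_frame(tables: Sequence[MetricTable]) -> pd.DataFrame:
    """Long-to-wide CSV-ready frame: one row per granularity."""
    rows = [{"granularity": t.granularity, **t.metrics} for t in tables]
    return pd.DataFrame(rows)
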