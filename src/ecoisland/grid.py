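"""Planar raster grid model and I/O.

All layers in the pipeline live on rectangular grids in a single planar
metric coordinate frame (row 0 = north, row-major addressing, a cell value
refers to the whole cell).  Continuous layers use a float grid with a
``-9999`` nodata sentinel; categorical land-use layers use integer class
codes with ``0`` as nodata so the sentinel never collides with the legal
codes 1-6.

Files are single-band TIFFs written with :mod:`tifffile`; the georeferencing
(cell size, origin, nodata, units) and the categorical legend travel in a
JSON sidecar next to the TIFF (``<name>.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

CONTINUOUS_NODATA = -9999.0
CATEGORICAL_NODATA = 0

#: land-use legend shared by the whole pipeline
LANDUSE_LEGEND = {
    1: "arable",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "built-up",
    6: "bareland",
}


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    ``origin_x``/``origin_y`` are the coordinates (m) of the outer corner of
    the top-left cell; ``cell_size`` is the square cell side in metres.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = CONTINUOUS_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def extent_x(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of cell centres as 1-D axis arrays."""
        x = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return x, y


@dataclass
class Raster:
    """A continuous single-band layer: grid geometry + values + units tag."""

    spec: GridSpec
    values: np.ndarray
    units: str = "1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )
        if not self.units:
            raise ValueError("units tag must be nonempty")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        return np.isfinite(self.values) & (self.values != self.spec.nodata)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=~self.mask)

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = fill
        return out

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Raster":
        return Raster(self.spec, values, units if units is not None else self.units)


@dataclass
class CategoricalRaster:
    """An integer-coded land-use layer with a legend."""

    spec: GridSpec
    codes: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(LANDUSE_LEGEND))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("categorical codes must be integers")
        if self.codes.shape != self.spec.shape:
            raise ValueError("codes shape does not match spec")
        present = set(np.unique(self.codes).tolist()) - {int(self.spec.nodata)}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes {sorted(missing)} missing from legend")

    @property
    def mask(self) -> np.ndarray:
        return self.codes != int(self.spec.nodata)

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.codes[self.mask], return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}


def categorical_spec(n_rows: int, n_cols: int, cell_size: float, **kw) -> GridSpec:
    return GridSpec(n_rows, n_cols, cell_size, nodata=CATEGORICAL_NODATA, **kw)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(raster: Raster | CategoricalRaster, path: str | Path) -> Path:
    """Write a layer as single-band TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spec = raster.spec
    meta = {
        "n_rows": spec.n_rows,
        "n_cols": spec.n_cols,
        "cell_size": spec.cell_size,
        "origin_x": spec.origin_x,
        "origin_y": spec.origin_y,
        "nodata": spec.nodata,
    }
    if isinstance(raster, CategoricalRaster):
        meta["kind"] = "categorical"
        meta["legend"] = {str(k): v for k, v in raster.legend.items()}
        data = raster.codes.astype(np.uint8)
    else:
        meta["kind"] = "continuous"
        meta["units"] = raster.units
        data = raster.values.astype(np.float32)
    tifffile.imwrite(path, data)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path: str | Path) -> Raster | CategoricalRaster:
    """Read a layer written by :func:`write_raster`.

    Rejects missing files, multi-band images, and continuous grids containing
    non-finite values outside nodata cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band grid, got shape {data.shape}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    spec = GridSpec(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        cell_size=float(meta["cell_size"]),
        origin_x=float(meta.get("origin_x", 0.0)),
        origin_y=float(meta.get("origin_y", 0.0)),
        nodata=float(meta["nodata"]) if meta["kind"] == "continuous" else int(meta["nodata"]),
    )
    if meta["kind"] == "categorical":
        legend = {int(k): v for k, v in meta["legend"].items()}
        return CategoricalRaster(spec, data.astype(np.int64), legend)
    values = data.astype(np.float64)
    bad = ~np.isfinite(values) & (values != spec.nodata)
    if bad.any():
        raise ValueError(f"{path}: non-finite values outside nodata cells")
    return Raster(spec, values, units=meta.get("units", "1"))


# ---------------------------------------------------------------------------
# alignment / resampling
# ---------------------------------------------------------------------------

def align(src: Raster, target: GridSpec, kind: str = "continuous") -> Raster:
    """Resample ``src`` onto the ``target`` grid.

    Continuous layers are interpolated bilinearly between source cell
    centres (edge values extended beyond the outermost centres); categorical
    handling is nearest-neighbour.  Target cells whose nearest source cell is
    nodata become nodata.
    """
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown kind {kind!r}")
    sspec, tspec = src.spec, target
    # spatial overlap check on bounding boxes
    sx0, sx1 = sspec.origin_x, sspec.origin_x + sspec.extent_x
    sy1, sy0 = sspec.origin_y, sspec.origin_y - sspec.extent_y
    tx0, tx1 = tspec.origin_x, tspec.origin_x + tspec.extent_x
    ty1, ty0 = tspec.origin_y, tspec.origin_y - tspec.extent_y
    if tx0 >= sx1 or tx1 <= sx0 or ty0 >= sy1 or ty1 <= sy0:
        raise ValueError("source and target grids do not overlap spatially")

    tx, ty = tspec.cell_centers()
    # fractional source row/col of each target centre
    col_f = (tx - sspec.origin_x) / sspec.cell_size - 0.5
    row_f = (sspec.origin_y - ty) / sspec.cell_size - 0.5

    if kind == "categorical":
        ci = np.clip(np.round(col_f).astype(int), 0, sspec.n_cols - 1)
        ri = np.clip(np.round(row_f).astype(int), 0, sspec.n_rows - 1)
        out = src.values[np.ix_(ri, ci)]
        return Raster(replace(tspec, nodata=sspec.nodata), out, src.units)

    vals = src.filled(np.nan)
    c0 = np.clip(np.floor(col_f).astype(int), 0, sspec.n_cols - 2) if sspec.n_cols > 1 else np.zeros_like(col_f, int)
    r0 = np.clip(np.floor(row_f).astype(int), 0, sspec.n_rows - 2) if sspec.n_rows > 1 else np.zeros_like(row_f, int)
    fc = np.clip(col_f - c0, 0.0, 1.0)
    fr = np.clip(row_f - r0, 0.0, 1.0)
    c1 = np.minimum(c0 + 1, sspec.n_cols - 1)
    r1 = np.minimum(r0 + 1, sspec.n_rows - 1)
    fr2 = fr[:, None]
    out = (
        vals[np.ix_(r0, c0)] * (1 - fr2) * (1 - fc)
        + vals[np.ix_(r0, c1)] * (1 - fr2) * fc
        + vals[np.ix_(r1, c0)] * fr2 * (1 - fc)
        + vals[np.ix_(r1, c1)] * fr2 * fc
    )
    result = np.where(np.isfinite(out), out, tspec.nodata)
    return Raster(tspec, result, src.units)


def majority_resample(src: CategoricalRaster, target_cell: float) -> CategoricalRaster:
    """Aggregate a categorical map to a coarser cell size by modal class.

    Each fine cell contributes to the coarse cell containing its centre (for
    integer cell-size ratios this is exact block counting).  Ties take the
    smallest class code; a coarse cell is nodata iff more than half of its
    contributing cells are nodata.  Trailing partial rows/columns beyond the
    last full coarse cell are truncated, so the coarse grid covers
    ``floor(extent / target_cell)`` cells per axis.
    """
    sspec = src.spec
    if target_cell < sspec.cell_size:
        raise ValueError("target cell must not be finer than the source cell")
    ratio = target_cell / sspec.cell_size
    if ratio == 1.0:
        return CategoricalRaster(sspec, src.codes.copy(), dict(src.legend))
    n_rows = int(sspec.extent_y // target_cell)
    n_cols = int(sspec.extent_x // target_cell)
    if n_rows < 1 or n_cols < 1:
        raise ValueError("target cell larger than the map extent")

    # coarse index of each fine cell centre
    fr = ((np.arange(sspec.n_rows) + 0.5) / ratio).astype(int)
    fc = ((np.arange(sspec.n_cols) + 0.5) / ratio).astype(int)
    keep_r = fr < n_rows
    keep_c = fc < n_cols
    codes = src.codes[np.ix_(keep_r, keep_c)]
    block = fr[keep_r][:, None] * n_cols + fc[keep_c][None, :]

    max_code = max(src.legend) if src.legend else int(codes.max(initial=0))
    nodata = int(sspec.nodata)
    n_blocks = n_rows * n_cols
    counts = np.zeros((n_blocks, max_code + 1), dtype=np.int64)
    for code in range(max_code + 1):
        sel = codes == code
        if sel.any():
            counts[:, code] = np.bincount(block[sel], minlength=n_blocks)
    total = counts.sum(axis=1)
    nodata_count = counts[:, nodata] if nodata <= max_code else np.zeros(n_blocks, int)
    valid_counts = counts.copy()
    if nodata <= max_code:
        valid_counts[:, nodata] = -1  # never the mode
    winner = valid_counts.argmax(axis=1)  # argmax returns smallest index on ties
    out = winner.astype(np.int64)
    out[nodata_count * 2 > total] = nodata
    out[total == nodata_count] = nodata
    tspec = GridSpec(n_rows, n_cols, target_cell, sspec.origin_x, sspec.origin_y, nodata=nodata)
    return CategoricalRaster(tspec, out.reshape(n_rows, n_cols), dict(src.legend))


def zonal_mean(layer: Raster, zones: CategoricalRaster | np.ndarray) -> dict[int, float]:
    """Mean of ``layer`` over the valid cells of each zone.

    ``zones`` is a CategoricalRaster on the same grid or a boolean/int array
    (booleans become a single zone with code 1).  Zones with no valid cells
    are omitted from the result rather than reported as zero.
    """
    if isinstance(zones, CategoricalRaster):
        if zones.spec.shape != layer.spec.shape:
            raise ValueError("layer and zone rasters have different grids")
        zcodes = zones.codes
        znodata = int(zones.spec.nodata)
    else:
        zarr = np.asarray(zones)
        if zarr.shape != layer.spec.shape:
            raise ValueError("layer and zone mask have different shapes")
        zcodes = zarr.astype(np.int64)
        znodata = 0
    valid = layer.mask & (zcodes != znodata)
    out: dict[int, float] = {}
    for code in np.unique(zcodes[zcodes != znodata]):
        sel = valid & (zcodes == code)
        if sel.any():
            out[int(code)] = float(layer.values[sel].mean())
    return out
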