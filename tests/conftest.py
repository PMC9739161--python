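from __future__ import annotations

import numpy as np
import pytest

from ecoisland.grid import CategoricalRaster, GridSpec, Raster, categorical_spec
from ecoisland.synth import IslandScenario, simulate


def make_raster(values, cell_size=30.0, nodata=-9999.0, units="1") -> Raster:
    values = np.asarray(values, dtype=float)
    spec = GridSpec(values.shape[0], values.shape[1], cell_size, nodata=nodata)
    return Raster(spec, values, units=units)


def make_catraster(codes, cell_size=30.0, legend=None) -> CategoricalRaster:
    codes = np.asarray(codes, dtype=np.int64)
    spec = categorical_spec(codes.shape[0], codes.shape[1], cell_size)
    if legend is None:
        legend = {int(c): f"class{c}" for c in np.unique(codes) if c != 0}
    return CategoricalRaster(spec, codes, legend)


def random_map(rng, shape=(8, 8), n_classes=2, cell_size=30.0,
               nodata_frac=0.0) -> CategoricalRaster:
    codes = rng.integers(1, n_classes + 1, size=shape)
    if nodata_frac > 0:
        codes[rng.random(shape) < nodata_frac] = 0
        if (codes != 0).sum() == 0:
            codes[0, 0] = 1
    return make_catraster(codes, cell_size)


@pytest.fixture(scope="session")
def small_scenario() -> IslandScenario:
    """Reduced-size island used across tests (fast; same structural presets)."""
    return IslandScenario(n_rows=120, n_cols=120, coarse_factor=20, seed=7)


@pytest.fixture(scope="session")
def small_island(small_scenario):
    return simulate(small_scenario)
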