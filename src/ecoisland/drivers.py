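"""Random-forest ranking of natural drivers via OOB permutation importance.

A regression forest is fitted to sampled cells (12 driver values ->
multi-epoch mean service value); each tree trains on a with-replacement
resample of 4/5 of the rows, and the rows a tree never saw form its
out-of-bag (OOB) set.  A driver's importance is the mean increase in OOB
mean-squared error when that driver's column is randomly permuted —
computed here directly from the per-tree OOB sets rather than on a
held-out split, so the estimate uses every sample.

The forest itself comes from scikit-learn; the OOB error and the
permutation importance are computed in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .grid import Raster


@dataclass
class SampleTable:
    """n sampled cells x (drivers + response), with cell coordinates."""

    data: pd.DataFrame            # driver columns + "response"
    rows: np.ndarray
    cols: np.ndarray
    seed: int
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = [c for c in self.data.columns if c != "response"]

    @property
    def x(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.data["response"].to_numpy()


def sample_pixels(drivers: dict[str, Raster], response: Raster, n: int,
                  seed: int, min_spacing: float = 0.0) -> SampleTable:
    """Seeded uniform sample of valid cells, without replacement.

    Candidate cells must be valid in the response and every driver layer;
    cells closer than ``min_spacing`` (in cells, Euclidean) to an already
    accepted cell are rejected.  Deterministic given the seed.
    """
    eligible = response.mask.copy()
    for r in drivers.values():
        if r.spec.shape != response.spec.shape:
            raise ValueError("driver and response layers are not aligned")
        eligible &= r.mask
    flat = np.flatnonzero(eligible)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(flat)
    n_cols = response.spec.n_cols
    acc_r: list[int] = []
    acc_c: list[int] = []
    for idx in order:
        r, c = divmod(int(idx), n_cols)
        if min_spacing > 0 and acc_r:
            d2 = (np.asarray(acc_r) - r) ** 2 + (np.asarray(acc_c) - c) ** 2
            if (d2 < min_spacing**2).any():
                continue
        acc_r.append(r)
        acc_c.append(c)
        if len(acc_r) == n:
            break
    if len(acc_r) < n:
        raise ValueError(
            f"only {len(acc_r)} cells satisfy the spacing constraint, need {n}")
    rows = np.asarray(acc_r)
    cols = np.asarray(acc_c)
    data = {name: r.values[rows, cols] for name, r in drivers.items()}
    data["response"] = response.values[rows, cols]
    return SampleTable(pd.DataFrame(data), rows, cols, seed)


@dataclass
class ForestModel:
    """Fitted regression forest plus the per-tree OOB bookkeeping."""

    forest: RandomForestRegressor
    feature_names: list[str]
    oob_mask: np.ndarray          # (n_trees, n_rows) True where row is OOB
    n_never_oob: int
    _leaf_values: list[np.ndarray] | None = None   # per-tree leaf-value cache


def fit_forest(table: SampleTable, n_trees: int = 500, seed: int = 0,
               resample_fraction: float = 0.8) -> ForestModel:
    """Fit a regression forest: 4/5-size bootstrap per tree, sqrt(p) splits."""
    x, y = table.x, table.y
    if len(y) < 30:
        raise ValueError("need at least 30 samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate constant response")
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        max_samples=resample_fraction,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(x, y)
    n = len(y)
    oob = np.ones((n_trees, n), dtype=bool)
    for t, inbag in enumerate(forest.estimators_samples_):
        oob[t, inbag] = False
    covered = oob.any(axis=0)
    return ForestModel(forest, list(table.feature_names), oob,
                       int((~covered).sum()))


def _tree_predictions(model: ForestModel, x: np.ndarray) -> np.ndarray:
    """(n_trees, n) per-tree predictions via one batched leaf lookup."""
    leaves = model.forest.apply(x)                       # (n, n_trees)
    if model._leaf_values is None:
        model._leaf_values = [est.tree_.value[:, 0, 0]
                              for est in model.forest.estimators_]
    return np.stack([vals[leaves[:, t]]
                     for t, vals in enumerate(model._leaf_values)])


def _oob_mse(model: ForestModel, preds: np.ndarray, y: np.ndarray) -> float:
    oob = model.oob_mask
    counts = oob.sum(axis=0)
    covered = counts > 0
    if not covered.any():
        raise ValueError("no row has OOB coverage")
    sums = np.einsum("tn,tn->n", preds, oob)
    oob_pred = sums[covered] / counts[covered]
    return float(np.mean((oob_pred - y[covered]) ** 2))


def oob_error(model: ForestModel, table: SampleTable) -> float:
    """OOB mean squared error: each row predicted only by trees it is OOB for."""
    return _oob_mse(model, _tree_predictions(model, table.x), table.y)


@dataclass
class ImportanceRanking:
    """Permutation importances and descending ranks for one service."""

    service: str
    scores: dict[str, float]       # mean OOB-MSE increase under permutation
    se: dict[str, float]           # standard error over repeats
    baseline_oob: float
    ranks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ranks:
            # descending score, ties broken alphabetically
            ordered = sorted(self.scores, key=lambda d: (-self.scores[d], d))
            self.ranks = {d: i + 1 for i, d in enumerate(ordered)}

    @property
    def top(self) -> str:
        return min(self.ranks, key=self.ranks.get)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"driver": d, "score": self.scores[d], "se": self.se[d],
                 "rank": self.ranks[d]}
                for d in sorted(self.ranks, key=self.ranks.get)]
        return pd.DataFrame(rows)


def permutation_importance(model: ForestModel, table: SampleTable,
                           n_repeats: int = 10, seed: int = 0,
                           service: str = "service") -> ImportanceRanking:
    """Mean OOB-error increase when each feature column is permuted."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    x, y = table.x, table.y
    base_preds = _tree_predictions(model, x)
    baseline = _oob_mse(model, base_preds, y)
    rng = np.random.default_rng(seed)
    scores: dict[str, float] = {}
    se: dict[str, float] = {}
    for j, name in enumerate(model.feature_names):
        increases = np.empty(n_repeats)
        for rep in range(n_repeats):
            xp = x.copy()
            xp[:, j] = xp[rng.permutation(len(y)), j]
            err = _oob_mse(model, _tree_predictions(model, xp), y)
            increases[rep] = err - baseline
        scores[name] = float(increases.mean())
        se[name] = float(increases.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    return ImportanceRanking(service, scores, se, baseline)


def rank_drivers_per_service(drivers: dict[str, Raster],
                             service_layers: dict[str, Raster],
                             n_samples: int = 1000, n_trees: int = 500,
                             n_repeats: int = 10, seed: int = 0,
                             min_spacing: float = 0.0
                             ) -> dict[str, ImportanceRanking]:
    """Sample -> fit -> permutation importance for each service layer."""
    out = {}
    for name, response in service_layers.items():
        table = sample_pixels(drivers, response, n_samples, seed=seed,
                              min_spacing=min_spacing)
        model = fit_forest(table, n_trees=n_trees, seed=seed)
        out[name] = permutation_importance(model, table, n_repeats=n_repeats,
                                           seed=seed, service=name)
    return out
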