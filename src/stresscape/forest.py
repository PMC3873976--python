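"""Random-forest models of landscape drivers of the stress surface.

Regresses the smoothed stress surface (pg/mg per 1-km cell) on the
covariate stack with a bagged ensemble of regression trees: per-tree
bootstrap of the training rows, a random subset of predictors considered
at each split (mtry), out-of-bag (OOB) error for honest variance explained,
and the two classic importance measures

* %IncMSE — per tree, the increase in OOB MSE after permuting a
  predictor's values among that tree's OOB rows, averaged over trees and
  normalized by its standard error across trees;
* IncNodePurity — the total decrease in node residual sum of squares from
  splits on a predictor, averaged over trees.

The ensemble is built from scikit-learn decision trees with explicit
per-tree in-bag index bookkeeping, because both importance measures and
the purity conservation identity need per-tree in-bag/out-of-bag sets.
Categorical predictors (landcover) are one-hot expanded before splitting
and importances are re-aggregated to the parent variable; ordinal RSF
codes are used directly.

Study protocol defaults: 1000 trees, 18 candidate predictors per split,
a 50/50 simple-random train/validation split of cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from sklearn.tree import DecisionTreeRegressor

from .raster import ConfigurationError, CovariateStack, GridRaster
from .smoothing import SmoothedSurface


class EmptyTableError(ValueError):
    """No cells valid in both the surface and the covariate stack."""


@dataclass
class ModelTable:
    """One row per valid 1-km cell: response (pg/mg) plus predictors."""

    frame: pd.DataFrame                 # response column 'hcc' + predictors
    kinds: dict[str, str]
    stratum: str = "all"
    dropped_cells: int = 0

    @property
    def response(self) -> np.ndarray:
        return self.frame["hcc"].to_numpy()

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.frame.columns if c != "hcc"]

    @property
    def n(self) -> int:
        return len(self.frame)


@dataclass
class ForestConfig:
    """Fitting protocol: trees, mtry, train fraction, leaf floor, seed."""

    n_trees: int = 1000
    mtry: int = 18
    train_fraction: float = 0.5
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ConfigurationError("mtry must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")


@dataclass
class ForestModel:
    """Fitted ensemble with OOB statistics and in-bag bookkeeping."""

    trees: list[DecisionTreeRegressor]
    inbag: list[np.ndarray]             # bootstrap sample indices per tree
    feature_names: list[str]            # expanded (one-hot) design columns
    parent_of: dict[str, str]           # design column -> reported variable
    X_train: np.ndarray
    y_train: np.ndarray
    oob_prediction: np.ndarray
    oob_mse: float
    oob_var_explained: float
    validation_r2: float
    effective_mtry: int
    config: ForestConfig = field(default_factory=ForestConfig)
    onehot_levels: dict[str, list[float]] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for col in self.feature_names:
            parent = self.parent_of[col]
            if parent not in seen:
                seen.append(parent)
        return seen

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.zeros(X.shape[0])
        for tree in self.trees:
            preds += tree.predict(X)
        return preds / len(self.trees)

    def design_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        """Expand a predictor frame into the fitted design columns."""
        cols = []
        for col in self.feature_names:
            if col in frame.columns:
                cols.append(frame[col].to_numpy(dtype=float))
            else:
                parent, _, level = col.rpartition("=")
                cols.append(
                    (frame[parent].to_numpy(dtype=float) == float(level))
                    .astype(float)
                )
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_model_table(
    surface: SmoothedSurface | GridRaster,
    stack: CovariateStack,
    stratum_mask: np.ndarray | None = None,
    stratum: str = "all",
) -> ModelTable:
    """Join the smoothed surface with per-cell predictor values.

    Keeps cells valid in the surface, valid in every stack layer, and
    (optionally) inside the stratum mask; counts dropped cells.
    """
    rast = surface.raster if isinstance(surface, SmoothedSurface) else surface
    template = stack.template
    if template is None or not template.co_registered(rast):
        raise ConfigurationError("surface and stack are not co-registered")
    mask = rast.valid_mask() & stack.valid_mask()
    candidates = int(mask.sum())
    if stratum_mask is not None:
        mask = mask & stratum_mask
    if not mask.any():
        raise EmptyTableError(f"no valid cells in stratum {stratum!r}")
    frame = stack.table(mask)
    frame.insert(0, "hcc", rast.values[mask])
    # dropped counts surface cells lost to stack nodata, not stratum exclusion
    dropped = int(rast.valid_mask().sum()) - candidates
    return ModelTable(
        frame=frame.reset_index(drop=True),
        kinds=dict(stack.kinds),
        stratum=stratum,
        dropped_cells=dropped,
    )


def _expand_design(table: ModelTable) -> tuple[np.ndarray, list[str], dict, dict]:
    """One-hot expand categorical predictors; pass the rest through."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    parent_of: dict[str, str] = {}
    onehot_levels: dict[str, list[float]] = {}
    for var in table.predictors:
        vals = table.frame[var].to_numpy(dtype=float)
        if table.kinds.get(var) == "categorical":
            levels = sorted(np.unique(vals))
            onehot_levels[var] = [float(l) for l in levels]
            for level in levels:
                col_name = f"{var}={level:g}"
                cols.append((vals == level).astype(float))
                names.append(col_name)
                parent_of[col_name] = var
        else:
            cols.append(vals)
            names.append(var)
            parent_of[var] = var
    return np.column_stack(cols), names, parent_of, onehot_levels


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_forest(table: ModelTable, cfg: ForestConfig | None = None) -> ForestModel:
    """Fit the bagged regression-tree ensemble.

    Splits rows 50/50 into train/validation by cfg.seed, bootstraps the
    training rows per tree, draws mtry candidate predictors uniformly at
    each split, and reports OOB variance explained
    (100 * (1 - oob_mse / var(y))) plus the squared correlation between
    withheld responses and their predictions.
    """
    cfg = cfg or ForestConfig()
    if table.n < 50:
        raise ConfigurationError("need at least 50 rows to fit the forest")
    X_all, names, parent_of, onehot_levels = _expand_design(table)
    y_all = table.response
    n_feat = X_all.shape[1]
    eff_mtry = min(cfg.mtry, n_feat)
    if cfg.mtry > n_feat:
        warnings.warn(
            f"mtry {cfg.mtry} exceeds {n_feat} design columns; using {n_feat}",
            RuntimeWarning, stacklevel=2,
        )
    if len(table.predictors) < 1:
        raise ConfigurationError("no predictors in table")

    rng = np.random.default_rng(cfg.seed)
    n = table.n
    perm = rng.permutation(n)
    n_train = max(2, int(round(cfg.train_fraction * n)))
    train_idx, valid_idx = perm[:n_train], perm[n_train:]
    X, y = X_all[train_idx], y_all[train_idx]
    Xv, yv = X_all[valid_idx], y_all[valid_idx]

    trees: list[DecisionTreeRegressor] = []
    inbag: list[np.ndarray] = []
    oob_sum = np.zeros(len(y))
    oob_cnt = np.zeros(len(y))
    tree_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_trees)
    boot_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    for t in range(cfg.n_trees):
        idx = boot_rng.integers(0, len(y), len(y))
        tree = DecisionTreeRegressor(
            max_features=eff_mtry,
            min_samples_leaf=cfg.min_leaf,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag.append(idx)
        oob = np.setdiff1d(np.arange(len(y)), idx, assume_unique=False)
        if oob.size:
            oob_sum[oob] += tree.predict(X[oob])
            oob_cnt[oob] += 1

    seen = oob_cnt > 0
    oob_pred = np.full(len(y), np.nan)
    oob_pred[seen] = oob_sum[seen] / oob_cnt[seen]
    oob_mse = float(np.mean((y[seen] - oob_pred[seen]) ** 2))
    var_y = float(np.var(y))
    oob_ve = 100.0 * (1.0 - oob_mse / var_y) if var_y > 0 else 0.0

    if len(yv) >= 2 and np.std(yv) > 0:
        pv = np.zeros(len(yv))
        for tree in trees:
            pv += tree.predict(Xv)
        pv /= len(trees)
        if np.std(pv) > 0:
            validation_r2 = float(np.corrcoef(yv, pv)[0, 1] ** 2)
        else:
            validation_r2 = 0.0
    else:
        validation_r2 = float("nan")

    return ForestModel(
        trees=trees, inbag=inbag, feature_names=names, parent_of=parent_of,
        X_train=X, y_train=y, oob_prediction=oob_pred, oob_mse=oob_mse,
        oob_var_explained=oob_ve, validation_r2=validation_r2,
        effective_mtry=eff_mtry, config=cfg, onehot_levels=onehot_levels,
    )


# ---------------------------------------------------------------------------
# importances
# ---------------------------------------------------------------------------

def permutation_importance(
    model: ForestModel, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """%IncMSE permutation importance, R-style.

    Per tree and variable: OOB MSE after permuting the variable's values
    within that tree's OOB rows, minus the tree's baseline OOB MSE. The
    report averages over trees and normalizes by the standard error across
    trees; a zero-variance normalizer falls back to the raw mean and is
    flagged. One-hot groups are permuted jointly with a single permutation
    so a categorical variable is destroyed as a unit.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    variables = model.variables
    var_cols = {
        v: [j for j, c in enumerate(model.feature_names)
            if model.parent_of[c] == v]
        for v in variables
    }
    n_trees = len(model.trees)
    diffs = np.full((n_trees, len(variables)), np.nan)
    X, y = model.X_train, model.y_train
    all_idx = np.arange(len(y))
    for t, (tree, idx) in enumerate(zip(model.trees, model.inbag)):
        oob = np.setdiff1d(all_idx, idx)
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean((yo - tree.predict(Xo)) ** 2)
        for vi, v in enumerate(variables):
            cols = var_cols[v]
            col_block = Xo[:, cols]
            if np.all(col_block == col_block[0]):
                diffs[t, vi] = 0.0  # constant within OOB: permutation no-op
                continue
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, cols] = col_block[perm]
            diffs[t, vi] = np.mean((yo - tree.predict(Xp)) ** 2) - base
    rows = []
    for vi, v in enumerate(variables):
        d = diffs[:, vi]
        d = d[np.isfinite(d)]
        mean = float(d.mean()) if d.size else 0.0
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        se = sd / np.sqrt(d.size) if d.size else 0.0
        if se > 0:
            score, flagged = mean / se, False
        else:
            score, flagged = mean, True
        rows.append(
            {"variable": v, "pct_inc_mse": score, "raw_mean_inc_mse": mean,
             "se": se, "zero_se_flag": flagged}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("pct_inc_mse", ascending=False)
        .reset_index(drop=True)
    )


def node_purity_importance(model: ForestModel) -> pd.DataFrame:
    """IncNodePurity: per-variable RSS decrease from splits, tree-averaged.

    For each split node, the drop in weighted impurity
    (N_parent * mse_parent - N_left * mse_left - N_right * mse_right) is an
    RSS decrease credited to the split variable. Summed over splits, the
    per-tree variable totals add up exactly to root RSS minus total leaf
    RSS (the conservation identity).
    """
    variables = model.variables
    totals = {v: 0.0 for v in variables}
    for tree in model.trees:
        t = tree.tree_
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            drop = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            parent = model.parent_of[model.feature_names[t.feature[node]]]
            totals[parent] += float(drop)
    n_trees = len(model.trees)
    frame = pd.DataFrame(
        [{"variable": v, "inc_node_purity": totals[v] / n_trees}
         for v in variables]
    )
    return (
        frame.sort_values("inc_node_purity", ascending=False)
        .reset_index(drop=True)
    )


def importance_table(
    model: ForestModel, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Both importance metrics, one row per reported variable."""
    perm = permutation_importance(model, seed)
    purity = node_purity_importance(model)
    return perm.merge(purity, on="variable")


# ---------------------------------------------------------------------------
# stratified models
# ---------------------------------------------------------------------------

def parks_mask(parks, template: GridRaster) -> np.ndarray:
    """Boolean mask of cells whose centre lies inside a park polygon."""
    geom_list = [f["geometry"] if isinstance(f, dict) else f for f in parks]
    if not geom_list:
        return np.zeros(template.shape, dtype=bool)
    union = shapely.unary_union(geom_list)
    shapely.prepare(union)
    centers = template.center_points()
    pts = shapely.points(centers[:, 0], centers[:, 1])
    return shapely.covers(union, pts).reshape(template.shape)


def stratified_fit(
    surface: SmoothedSurface | GridRaster,
    stack: CovariateStack,
    parks,
    cfg: ForestConfig | None = None,
    min_rows: int = 50,
    importance_seed: int = 0,
) -> dict[str, dict]:
    """Total plus inside/outside-protected-area models.

    Fits three models with identical configuration but different cell
    strata; strata with fewer than ``min_rows`` valid cells are skipped
    with a warning. Returns {stratum: {"model": ..., "importance": ...}}.
    """
    cfg = cfg or ForestConfig()
    rast = surface.raster if isinstance(surface, SmoothedSurface) else surface
    inside = parks_mask(parks, rast)
    results: dict[str, dict] = {}
    for stratum, mask in (
        ("total", None), ("inside_pa", inside), ("outside_pa", ~inside),
    ):
        try:
            table = build_model_table(surface, stack, mask, stratum=stratum)
        except EmptyTableError:
            warnings.warn(f"stratum {stratum!r} has no cells; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        if table.n < min_rows:
            warnings.warn(
                f"stratum {stratum!r} has {table.n} rows (< {min_rows}); skipped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        model = fit_forest(table, cfg)
        results[stratum] = {
            "model": model,
            "table": table,
            "importance": importance_table(model, importance_seed),
        }
    return results
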