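"""Attribute variation in site-level growth-VPD t-values to seven site
predictors with a bagged regression forest.

The forest itself is scikit-learn's ``RandomForestRegressor`` (500 trees,
bootstrap resampling, ~p/3 candidate predictors per split).  On top of it
this module computes the three diagnostics reported for such analyses:
unscaled out-of-bag MSE increase under per-tree permutation, average
minimal depth (root = 0; variables absent from a tree get that tree's
depth + 1), and root-node occurrence counts — plus partial-dependence
curves.  The categorical species predictor is one-hot encoded and its
indicator columns are treated as one variable group (jointly permuted,
minimum depth over indicators, importance summed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "PREDICTORS",
    "ForestResult",
    "assemble_sensitivity_table",
    "fit_forest",
    "permutation_importance",
    "minimal_depth_stats",
    "partial_dependence",
    "importance_report",
]

PREDICTORS = ["elevation", "mat", "map", "summer_smi", "species", "mean_age", "mean_ba"]


class DriverError(ValueError):
    pass


@dataclass
class ForestResult:
    model: RandomForestRegressor
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    groups: dict[str, list[int]]          # variable -> column indices
    species_levels: list[str] = field(default_factory=list)
    oob_indices: list[np.ndarray] = field(default_factory=list)


def assemble_sensitivity_table(fits, site_summaries: pd.DataFrame,
                               climatologies: pd.DataFrame,
                               alpha_level: float = 0.05,
                               covariates=("vpd_t", "vpd_t1")) -> pd.DataFrame:
    """One row per significant covariate x site-species combination.

    ``fits`` are converged/attempted :class:`GrowthModelFit` objects;
    ``site_summaries`` carries site_id, species, mean_age, mean_ba;
    ``climatologies`` carries site_id, elevation, mat, map, summer_smi.
    Rows with missing predictors are dropped with a warning."""
    rows = []
    for fit in fits:
        if not fit.converged:
            continue
        for cov, t, p in (("vpd_t", fit.t_beta1, fit.p_beta1),
                          ("vpd_t1", fit.t_beta2, fit.p_beta2)):
            if cov not in covariates:
                continue
            if np.isfinite(t) and np.isfinite(p) and p < alpha_level:
                rows.append({"site_id": fit.site_id, "species": fit.species,
                             "which_covariate": cov, "t_value": t})
    if not rows:
        return pd.DataFrame(columns=["site_id", "species", "which_covariate", "t_value",
                                     *PREDICTORS])
    df = pd.DataFrame(rows)
    df = df.merge(site_summaries[["site_id", "species", "mean_age", "mean_ba"]],
                  on=["site_id", "species"], how="left")
    df = df.merge(climatologies, on="site_id", how="left")
    need = ["elevation", "mat", "map", "summer_smi", "mean_age", "mean_ba"]
    bad = df[need].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} significant rows with missing predictors")
        df = df[~bad]
    return df.reset_index(drop=True)


def _encode(table: pd.DataFrame):
    levels = sorted(table["species"].astype(str).unique())
    cols, names = [], []
    groups: dict[str, list[int]] = {}
    for var in PREDICTORS:
        if var == "species":
            idxs = []
            for lv in levels:
                cols.append((table["species"].astype(str) == lv).to_numpy(float))
                idxs.append(len(names))
                names.append(f"species[{lv}]")
            groups["species"] = idxs
        else:
            cols.append(table[var].to_numpy(float))
            groups[var] = [len(names)]
            names.append(var)
    return np.column_stack(cols), names, groups, levels


def fit_forest(table: pd.DataFrame, n_trees: int = 500, seed: int = 0,
               mtry: int | None = None, min_samples_leaf: int = 5,
               bootstrap: bool = True, **rf_kwargs) -> ForestResult:
    """Bagged CART regression forest predicting the t-values.

    Defaults mirror regression-forest convention: per-tree bootstrap,
    ``ceil(p/3)`` candidate predictors per split.  Out-of-bag row indices
    are retained per tree for the permutation importance."""
    if table.empty:
        raise DriverError("empty sensitivity table: nothing significant to model")
    y = table["t_value"].to_numpy(float)
    if np.ptp(y) == 0:
        raise DriverError("constant response: forest cannot be fit")
    if len(table) < 30:
        warnings.warn(f"only {len(table)} rows; forest diagnostics will be noisy")
    X, names, groups, levels = _encode(table)
    p_vars = len(PREDICTORS)
    if mtry is None:
        mtry = int(np.ceil(p_vars / 3))
    mtry = min(max(mtry, 1), X.shape[1])
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, bootstrap=bootstrap,
        min_samples_leaf=min_samples_leaf, random_state=seed, n_jobs=1, **rf_kwargs,
    )
    rf.fit(X, y)
    n = len(y)
    oob = []
    if bootstrap:
        for sampled in rf.estimators_samples_:
            mask = np.ones(n, dtype=bool)
            mask[sampled] = False
            oob.append(np.flatnonzero(mask))
    else:
        oob = [np.empty(0, dtype=int)] * n_trees
    return ForestResult(model=rf, X=X, y=y, feature_names=names, groups=groups,
                        species_levels=levels, oob_indices=oob)


def permutation_importance(forest: ForestResult, seed: int = 0) -> dict[str, float]:
    """Unscaled OOB MSE increase per variable, averaged over trees.

    Grouped columns (species indicators) are permuted jointly with one
    shared permutation per tree."""
    rng = np.random.default_rng(seed)
    X, y = forest.X, forest.y
    sums = {v: 0.0 for v in forest.groups}
    counts = {v: 0 for v in forest.groups}
    for est, oob in zip(forest.model.estimators_, forest.oob_indices):
        if len(oob) < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = float(np.mean((est.predict(Xo) - yo) ** 2))
        perm = rng.permutation(len(oob))
        for var, cols in forest.groups.items():
            Xp = Xo.copy()
            Xp[:, cols] = Xo[perm][:, cols]
            mse = float(np.mean((est.predict(Xp) - yo) ** 2))
            sums[var] += mse - base
            counts[var] += 1
    return {v: (sums[v] / counts[v] if counts[v] else np.nan) for v in forest.groups}


def minimal_depth_stats(forest: ForestResult) -> pd.DataFrame:
    """Average minimal depth and root-node occurrences per variable.

    Minimal depth is the depth of the shallowest split on the variable
    (root = 0); a variable never used in a tree is assigned that tree's
    maximum depth + 1.  Root counts sum to the number of trees."""
    col_to_var = {}
    for var, cols in forest.groups.items():
        for c in cols:
            col_to_var[c] = var
    depth_sums = {v: 0.0 for v in forest.groups}
    root_counts = {v: 0 for v in forest.groups}
    n_trees = len(forest.model.estimators_)
    for est in forest.model.estimators_:
        t = est.tree_
        depths = np.zeros(t.node_count, dtype=int)
        stack = [(0, 0)]
        mind = {}
        max_depth = 0
        while stack:
            node, d = stack.pop()
            depths[node] = d
            max_depth = max(max_depth, d)
            f = t.feature[node]
            if f >= 0:
                var = col_to_var[f]
                if var not in mind or d < mind[var]:
                    mind[var] = d
                stack.append((t.children_left[node], d + 1))
                stack.append((t.children_right[node], d + 1))
        root_f = t.feature[0]
        if root_f >= 0:
            root_counts[col_to_var[root_f]] += 1
        for v in forest.groups:
            depth_sums[v] += mind.get(v, max_depth + 1)
    rows = [{"variable": v,
             "avg_min_depth": depth_sums[v] / n_trees,
             "root_node_count": root_counts[v]} for v in forest.groups]
    return pd.DataFrame(rows)


def partial_dependence(forest: ForestResult, variable: str, grid=None,
                       n_grid: int = 30) -> pd.DataFrame:
    """Marginal effect of one predictor on predicted t-values.

    For numeric variables: mean forest prediction with the variable forced
    to each grid value, plus the variable's sample 2.5/97.5 percentile
    coverage flags; for species: one value per level."""
    if variable not in forest.groups:
        raise DriverError(f"unknown variable {variable!r}")
    X = forest.X
    if variable == "species":
        cols = forest.groups["species"]
        rows = []
        for lv, col in sorted(zip(forest.species_levels, cols)):
            Xg = X.copy()
            Xg[:, cols] = 0.0
            Xg[:, col] = 1.0
            rows.append({"level": lv, "pd": float(forest.model.predict(Xg).mean())})
        return pd.DataFrame(rows)
    col = forest.groups[variable][0]
    vals = X[:, col]
    lo, hi = np.quantile(vals, [0.025, 0.975])
    if grid is None:
        grid = np.linspace(vals.min(), vals.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < vals.min() or grid.max() > vals.max():
        warnings.warn(f"partial dependence grid extends beyond observed {variable} range")
    out = []
    for g in grid:
        Xg = X.copy()
        Xg[:, col] = g
        out.append({
            "grid": float(g),
            "pd": float(forest.model.predict(Xg).mean()),
            "in_95pct_coverage": bool(lo <= g <= hi),
            "extrapolated": bool(g < vals.min() or g > vals.max()),
        })
    return pd.DataFrame(out)


def importance_report(forest: ForestResult, seed: int = 0) -> pd.DataFrame:
    """Combined table: average minimal depth, unscaled MSE increase and
    root-node count per variable (one row per predictor)."""
    depth = minimal_depth_stats(forest).set_index("variable")
    imp = permutation_importance(forest, seed=seed)
    depth["mse_increase"] = pd.Series(imp)
    return depth.reset_index()[["variable", "avg_min_depth", "mse_increase", "root_node_count"]]
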