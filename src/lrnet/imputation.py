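"""Missing-value handling for the mean-rank matrix.

Consensus interaction inference is sparse: an interaction absent from a
biopsy's output leaves a hole in the sample x interaction matrix, and the
downstream latent-variable models need a complete one.  The strategy:

1. drop interactions observed in fewer than a fraction ``tau`` of samples;
2. pick ``tau`` and the imputer by masking known values in the fully
   observed submatrix (at the same rate as the real missingness), imputing
   them back, and scoring the normalized root-mean-square error (NRMSE) --
   RMSE divided by the population sd of the masked truth, so 1 means "no
   better than predicting the mean";
3. impute the thresholded matrix with the winner.

Three imputers are provided: column mean, distance-weighted kNN, and the
iterative random-forest scheme (column-by-column regression on all other
columns, repeated until the imputed values stop improving).  Following the
reference workflow the matrix is transposed first, so interactions are rows
and samples are the regression variables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

__all__ = [
    "ImputationReport",
    "missingness_filter",
    "mask_complete_subset",
    "impute",
    "impute_columns",
    "nrmse",
    "threshold_sweep",
    "IMPUTERS",
]

IMPUTERS = ("mean", "knn", "random_forest")


def missingness_filter(matrix: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Keep columns observed in at least a fraction ``tau`` of samples
    (boundary inclusive)."""
    if not (0 <= tau <= 1):
        raise ValueError("tau must lie in [0, 1]")
    present = matrix.notna().mean(axis=0)
    return matrix.loc[:, present >= tau]


def mask_complete_subset(
    matrix: pd.DataFrame, proportion: float, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Randomly mask cells of the fully observed columns for NRMSE scoring.

    Returns the masked copy (complete columns only) and the ground truth as
    a Series indexed by (sample, column).  The mask size is
    round(proportion x cell count); a proportion that rounds to zero cells
    is an error because there would be nothing to score.
    """
    if not (0 < proportion < 1):
        raise ValueError("proportion must lie in (0, 1)")
    complete = matrix.loc[:, matrix.notna().all(axis=0)]
    if complete.shape[1] == 0:
        raise ValueError(
            "no fully observed columns; lower the missingness threshold tau"
        )
    n_cells = complete.size
    n_mask = int(round(proportion * n_cells))
    if n_mask == 0:
        raise ValueError("mask proportion rounds to zero cells; nothing to evaluate")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    rows, cols = np.unravel_index(flat, complete.shape)
    masked = complete.copy()
    idx = []
    vals = []
    for r, c in zip(rows, cols):
        idx.append((complete.index[r], complete.columns[c]))
        vals.append(complete.iat[r, c])
        masked.iat[r, c] = np.nan
    truth = pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["sample", "feature"]))
    return masked, truth


def _mean_impute(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    col_means = np.nanmean(out, axis=0)
    holes = np.isnan(out)
    out[holes] = np.take(col_means, np.nonzero(holes)[1])
    return out


def _knn_impute(values: np.ndarray, k: int) -> np.ndarray:
    imputer = KNNImputer(n_neighbors=k, weights="distance")
    return imputer.fit_transform(values)


def _rf_impute(
    values: np.ndarray,
    n_trees: int,
    max_iter: int,
    seed: int,
) -> np.ndarray:
    """Iterative random-forest imputation of columns, missForest-style.

    Missing cells start at their column mean; columns are revisited in
    ascending-missingness order, each regressed on all others over its
    observed rows; iteration stops when the summed squared change of the
    imputed cells increases (the previous, non-worsening state is returned)
    or after ``max_iter`` passes.
    """
    holes = np.isnan(values)
    current = _mean_impute(values)
    order = np.argsort(holes.sum(axis=0))
    order = [j for j in order if holes[:, j].any()]
    if not order:
        return current
    rng = np.random.default_rng(seed)
    prev_delta = np.inf
    prev_state = current.copy()
    for _ in range(max_iter):
        before = current[holes].copy()
        for j in order:
            obs = ~holes[:, j]
            predictors = np.delete(current, j, axis=1)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(predictors[obs], current[obs, j])
            current[holes[:, j], j] = forest.predict(predictors[holes[:, j]])
        delta = float(np.sum((current[holes] - before) ** 2))
        if delta > prev_delta:
            return prev_state
        prev_state = current.copy()
        prev_delta = delta
        if delta == 0.0:
            break
    return prev_state


def impute_columns(
    matrix: pd.DataFrame,
    method: str,
    k: int = 5,
    n_trees: int = 500,
    max_iter: int = 20,
    seed: int = 123,
) -> pd.DataFrame:
    """Impute missing cells column-wise in the given orientation."""
    if method not in IMPUTERS:
        raise ValueError(f"unknown imputer {method!r}; choose from {IMPUTERS}")
    values = matrix.to_numpy(float)
    holes = np.isnan(values)
    empty = holes.all(axis=0)
    if empty.any():
        bad = [str(matrix.columns[j]) for j in np.nonzero(empty)[0]]
        raise ValueError(f"columns with zero observed values: {bad}")
    if not holes.any():
        return matrix.copy()
    if method == "mean":
        filled = _mean_impute(values)
    elif method == "knn":
        filled = _knn_impute(values, k)
    else:
        filled = _rf_impute(values, n_trees=n_trees, max_iter=max_iter, seed=seed)
    filled[~holes] = values[~holes]  # observed cells are never altered
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def impute(
    matrix: pd.DataFrame,
    method: str,
    orientation: str = "features_as_rows",
    **params,
) -> pd.DataFrame:
    """Impute a sample x interaction matrix to completeness.

    With the default orientation the matrix is transposed so interactions
    are rows and the per-sample profiles are the regression variables, then
    transposed back.  ``orientation="as_is"`` imputes columns directly.
    """
    if orientation == "features_as_rows":
        return impute_columns(matrix.T, method, **params).T
    if orientation == "as_is":
        return impute_columns(matrix, method, **params)
    raise ValueError("orientation must be 'features_as_rows' or 'as_is'")


def nrmse(imputed: pd.DataFrame, truth: pd.Series) -> float:
    """RMSE over the masked cells divided by the population sd of the truth."""
    if truth.empty:
        raise ValueError("mask is empty")
    true_vals = truth.to_numpy(float)
    sd = float(np.std(true_vals))  # population (n-denominator) sd
    if sd == 0:
        raise ValueError("masked truth values are constant; NRMSE undefined")
    est = np.array([imputed.at[s, f] for s, f in truth.index])
    rmse = float(np.sqrt(np.mean((est - true_vals) ** 2)))
    return rmse / sd


@dataclass
class ImputationReport:
    """Record of an NRMSE threshold/imputer sweep."""

    candidate_imputers: list[str]
    threshold_grid: list[float]
    nrmse_table: dict[tuple[str, float], float]
    chosen_imputer: str
    chosen_threshold: float
    mask_seed: int
    masked_fraction: dict[float, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "candidate_imputers": self.candidate_imputers,
            "threshold_grid": self.threshold_grid,
            "nrmse": [
                {"imputer": imp, "threshold": thr, "nrmse": val}
                for (imp, thr), val in sorted(self.nrmse_table.items())
            ],
            "chosen_imputer": self.chosen_imputer,
            "chosen_threshold": self.chosen_threshold,
            "mask_seed": self.mask_seed,
            "masked_fraction": {str(k): v for k, v in sorted(self.masked_fraction.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _evaluate_threshold(
    matrix: pd.DataFrame,
    imputer: str,
    tau: float,
    seed: int,
    imputer_params: Mapping,
) -> tuple[float, float] | None:
    """(NRMSE, masked fraction) at one threshold, or None if not evaluable."""
    filtered = missingness_filter(matrix, tau)
    if filtered.shape[1] == 0:
        return None
    miss_frac = float(filtered.isna().mean().mean())
    if miss_frac == 0 or miss_frac >= 1:
        return None
    try:
        masked, truth = mask_complete_subset(
            filtered, miss_frac, seed=(seed + int(round(tau * 100))) % (2**31 - 1)
        )
    except ValueError:
        return None
    try:
        # masking can strip every value of one sample in a narrow complete
        # subset, which no column-wise imputer can fill -- not evaluable
        imputed = impute(masked, imputer, **dict(imputer_params))
        return nrmse(imputed, truth), miss_frac
    except ValueError:
        return None


def threshold_sweep(
    matrix: pd.DataFrame,
    imputer: str | Sequence[str] = "random_forest",
    seed: int = 123,
    imputer_params: Mapping | None = None,
) -> ImputationReport:
    """Coarse-then-fine NRMSE sweep over missingness thresholds.

    Coarse grid 0 to 1 in steps of 0.1; the fine grid covers +/- 0.05 around
    the best coarse threshold in steps of 0.01, clipped to [0, 1].  The
    chosen (imputer, threshold) minimizes NRMSE over the union grid, ties
    resolved toward the smaller threshold (more features survive).  Grid
    points where masking is impossible are recorded as not evaluable and
    excluded from the argmin.
    """
    imputers = [imputer] if isinstance(imputer, str) else list(imputer)
    params = imputer_params or {}
    if matrix.size == 0:
        raise ValueError("matrix is empty")

    coarse = [round(t, 2) for t in np.arange(0.0, 1.0 + 1e-9, 0.1)]
    table: dict[tuple[str, float], float] = {}
    masked_frac: dict[float, float] = {}

    def run_grid(grid: Sequence[float]) -> None:
        for tau in grid:
            for imp in imputers:
                if (imp, tau) in table:
                    continue
                result = _evaluate_threshold(matrix, imp, tau, seed, params)
                if result is None:
                    continue
                table[(imp, tau)], masked_frac[tau] = result

    run_grid(coarse)
    if not table:
        raise ValueError(
            "no threshold was evaluable (matrix has no missing values to mimic, "
            "or no complete columns at any threshold)"
        )
    best_imp, best_coarse = min(table, key=lambda key: (table[key], key[1], key[0]))
    fine = [
        round(t, 2)
        for t in np.arange(best_coarse - 0.05, best_coarse + 0.05 + 1e-9, 0.01)
        if 0.0 <= round(t, 2) <= 1.0
    ]
    run_grid(fine)
    chosen_imp, chosen_tau = min(table, key=lambda key: (table[key], key[1], key[0]))
    grid = sorted({t for _, t in table})
    return ImputationReport(
        candidate_imputers=imputers,
        threshold_grid=grid,
        nrmse_table=table,
        chosen_imputer=chosen_imp,
        chosen_threshold=chosen_tau,
        mask_seed=seed,
        masked_fraction=masked_frac,
    )
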