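"""Stability selection by repeated penalized logistic regression.

The discriminative signature is not the coefficient vector of a single
LASSO fit -- with more features than samples that is too unstable -- but
the set of features selected in at least 90% of many repeated fits.  Each
repeat chooses its penalty strength by internal cross-validation whose fold
partition is re-randomized, so the repeat-to-repeat variability reflects
the sensitivity of the penalty choice to the data split.  Selected-feature
identities (not coefficients) feed the downstream discriminant model.

Biologically infeasible features are removed through an explicit exclusion
list (an expert-curated artifact, never inferred), rerunning selection
until the retained set is clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, enet_path
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import l1_min_c

logger = logging.getLogger(__name__)

__all__ = [
    "StabilitySelection",
    "PruningRecord",
    "EXCLUSION_REASONS",
    "log10_transform",
    "stability_lasso",
    "prune_and_rerun",
    "read_exclusion_list",
]

#: Reason codes for excluding an interaction as biologically infeasible.
EXCLUSION_REASONS = (
    "single_cell_complex_subunit",
    "intracellular_localization",
    "refuted_interaction",
)


def log10_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10 of a complete, strictly positive matrix."""
    values = matrix.to_numpy(float)
    if np.isnan(values).any():
        raise ValueError("matrix must be complete before log transform")
    if (values <= 0).any():
        raise ValueError("log10_transform requires strictly positive values")
    return pd.DataFrame(np.log10(values), index=matrix.index, columns=matrix.columns)


@dataclass
class StabilitySelection:
    """Per-feature selection frequencies from repeated penalized fits."""

    feature_ids: list[str]
    selection_frequency: pd.Series
    retention_threshold: float
    alpha: float
    n_repeats: int
    seed: int

    @property
    def retained(self) -> set[str]:
        return set(
            self.selection_frequency[
                self.selection_frequency >= self.retention_threshold
            ].index
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "frequency": self.selection_frequency.reindex(self.feature_ids).to_numpy(),
                "retained": [f in self.retained for f in self.feature_ids],
            }
        )


def _encode_labels(y: Sequence) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    return (y == classes[1]).astype(int), classes


def _standardize(X: pd.DataFrame) -> np.ndarray:
    values = X.to_numpy(float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant columns carry no signal; keep them inert
    return (values - mean) / sd


def _make_estimator(C: float, alpha: float) -> LogisticRegression:
    if alpha >= 1.0:
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-4
        )
    return LogisticRegression(
        l1_ratio=alpha,
        C=C,
        solver="saga",
        max_iter=5000,
        tol=1e-4,
    )


def _squared_loss_cv(
    Xs: np.ndarray,
    y01: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    folds: StratifiedKFold,
) -> np.ndarray:
    """Held-out MSE per lambda for the elastic-net path with +/-1 response."""
    yv = np.where(y01 == 1, 1.0, -1.0)
    losses = np.zeros((len(lambdas), folds.get_n_splits()))
    for f, (train, test) in enumerate(folds.split(Xs, y01)):
        y_train = yv[train]
        offset = y_train.mean()
        _, coefs, _ = enet_path(
            Xs[train], y_train - offset, l1_ratio=alpha, alphas=lambdas, max_iter=5000
        )
        pred = Xs[test] @ coefs + offset
        losses[:, f] = np.mean((yv[test][:, None] - pred) ** 2, axis=0)
    return losses


def _logistic_loss_cv(
    Xs: np.ndarray,
    y01: np.ndarray,
    alpha: float,
    c_grid: np.ndarray,
    folds: StratifiedKFold,
) -> np.ndarray:
    losses = np.zeros((len(c_grid), folds.get_n_splits()))
    for f, (train, test) in enumerate(folds.split(Xs, y01)):
        for ci, C in enumerate(c_grid):
            est = _make_estimator(C, alpha).fit(Xs[train], y01[train])
            prob = est.predict_proba(Xs[test])[:, 1]
            losses[ci, f] = log_loss(y01[test], prob, labels=[0, 1])
    return losses


def stability_lasso(
    X: pd.DataFrame,
    y: Sequence,
    alpha: float = 1.0,
    n_repeats: int = 500,
    retention: float = 0.9,
    seed: int = 0,
    loss: str = "squared",
    internal_folds: int = 5,
    n_penalties: int = 30,
    penalty_rule: str = "1se",
) -> StabilitySelection:
    """Selection frequencies over repeated CV-tuned elastic-net fits.

    The default fit is the regression-style penalized least-squares model on
    a +/-1-coded response (the classic ``lasso`` of glmnet/MATLAB); a
    penalized logistic variant is available with ``loss="logistic"``.  Per
    repeat, a re-randomized stratified ``internal_folds``-fold partition
    scores a fixed log-spaced penalty grid (glmnet convention, two decades
    below the smallest all-zero penalty) by held-out deviance; the chosen
    penalty is the strongest one within one standard error of the minimum
    (``penalty_rule="1se"``, the stability-selection-friendly default --
    the raw minimum tends to drag spuriously correlated features into every
    repeat) or the minimum itself (``"min"``).  The model is then refit on
    all samples at that penalty and its nonzero-coefficient features count
    as selected; since the refit does not depend on the partition, refits
    are cached per penalty.  Frequencies are selections / n_repeats and
    features at or above ``retention`` form the retained set.  Features are
    standardized so the penalty treats them comparably.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha (l1 mixing) must lie in (0, 1]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if loss not in ("squared", "logistic"):
        raise ValueError("loss must be 'squared' or 'logistic'")
    if penalty_rule not in ("min", "1se"):
        raise ValueError("penalty_rule must be 'min' or '1se'")
    y01, _ = _encode_labels(y)
    class_counts = np.bincount(y01, minlength=2)
    if class_counts.min() < internal_folds:
        raise ValueError(
            f"each class needs >= {internal_folds} samples for internal CV "
            f"(got {class_counts.tolist()})"
        )
    Xs = _standardize(X)
    n, p = Xs.shape

    if loss == "squared":
        yv = np.where(y01 == 1, 1.0, -1.0)
        lam_max = float(np.max(np.abs(Xs.T @ (yv - yv.mean())))) / n / max(alpha, 1e-6)
        grid = lam_max * np.logspace(0.0, -2.0, n_penalties)
    else:
        base_c = l1_min_c(Xs, y01, loss="log") / max(alpha, 1e-6)
        grid = base_c * np.logspace(-0.2, 2.0, n_penalties)

    nonzero_cache: dict[int, np.ndarray] = {}

    def nonzero_at(gi: int) -> np.ndarray:
        if gi not in nonzero_cache:
            if loss == "squared":
                yv = np.where(y01 == 1, 1.0, -1.0)
                _, coefs, _ = enet_path(
                    Xs, yv - yv.mean(), l1_ratio=alpha, alphas=grid[: gi + 1], max_iter=5000
                )
                nonzero_cache[gi] = np.abs(coefs[:, -1]) > 1e-10
            else:
                est = _make_estimator(grid[gi], alpha).fit(Xs, y01)
                nonzero_cache[gi] = np.abs(est.coef_.ravel()) > 1e-10
        return nonzero_cache[gi]

    selected = np.zeros(p, dtype=float)
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    for rep in range(n_repeats):
        rep_seed = int(children[rep].generate_state(1)[0] % (2**31 - 1))
        folds = StratifiedKFold(
            n_splits=internal_folds, shuffle=True, random_state=rep_seed
        )
        if loss == "squared":
            losses = _squared_loss_cv(Xs, y01, alpha, grid, folds)
        else:
            losses = _logistic_loss_cv(Xs, y01, alpha, grid, folds)
        mean_loss = losses.mean(axis=1)
        best = int(np.argmin(mean_loss))  # ties -> stronger penalty (smaller index)
        if penalty_rule == "1se":
            se = losses.std(axis=1, ddof=1) / np.sqrt(internal_folds)
            best = int(np.nonzero(mean_loss <= mean_loss[best] + se[best])[0][0])
        selected += nonzero_at(best)

    freq = pd.Series(selected / n_repeats, index=X.columns, name="frequency")
    return StabilitySelection(
        feature_ids=list(X.columns),
        selection_frequency=freq,
        retention_threshold=retention,
        alpha=alpha,
        n_repeats=n_repeats,
        seed=seed,
    )


@dataclass
class PruningRecord:
    iteration: int
    excluded_features: list[tuple[str, str]]  # (feature label, reason code)
    retained_after: set[str] = field(default_factory=set)


def prune_and_rerun(
    X: pd.DataFrame,
    y: Sequence,
    exclusion_list: Mapping[str, str],
    **selector_kwargs,
) -> tuple[StabilitySelection, list[PruningRecord]]:
    """Iteratively drop excluded features from the retained set and rerun.

    ``exclusion_list`` maps feature labels to reason codes.  Each iteration
    runs :func:`stability_lasso`; if any retained feature is on the list,
    those features are removed from the design matrix and selection reruns.
    Excluded features never seen in ``X`` are ignored with a warning.
    """
    unknown = [f for f in exclusion_list if f not in X.columns]
    if unknown:
        logger.warning("exclusion-list features absent from X, ignored: %s", unknown)
    current = X.copy()
    records: list[PruningRecord] = []
    iteration = 0
    while True:
        iteration += 1
        if current.shape[1] == 0:
            raise ValueError("all features excluded; nothing left to select from")
        selection = stability_lasso(current, y, **selector_kwargs)
        bad = sorted(selection.retained & set(exclusion_list))
        records.append(
            PruningRecord(
                iteration=iteration,
                excluded_features=[(f, exclusion_list[f]) for f in bad],
                retained_after=selection.retained - set(bad),
            )
        )
        if not bad:
            return selection, records
        current = current.drop(columns=bad)


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read a TSV exclusion list (feature key columns + reason code).

    Expected columns: sender, receiver, ligand_complex, receptor_complex,
    reason; a free-text rationale column is allowed and ignored here.
    """
    from .io import InteractionKey, key_to_label

    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ("sender", "receiver", "ligand_complex", "receptor_complex", "reason")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        key = InteractionKey(
            row.sender,
            row.receiver,
            tuple(str(row.ligand_complex).split("_")),
            tuple(str(row.receptor_complex).split("_")),
        )
        reason = str(row.reason)
        if reason not in EXCLUSION_REASONS:
            logger.warning("nonstandard exclusion reason %r for %s", reason, key)
        out[key_to_label(key)] = reason
    return out
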