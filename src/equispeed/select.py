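"""Sequential floating forward selection (SFFS) with an RMSE criterion.

A wrapper selector: candidate features are scored by the k-fold
cross-validated RMSE of a regressor trained on the current subset plus the
candidate.  A feature is added only when it lowers the CV RMSE by more than
the criterion (0.01 m/s); after each addition, already-selected features are
floated out again while removing one lowers the RMSE by more than the same
margin.  Folds are grouped by subject so that selection never sees windows
of a test subject during scoring.

The selected trajectory is therefore strictly decreasing in steps larger
than the criterion, and an empty selection is a legitimate outcome on pure
noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import GroupKFold

from .features import feature_columns
from .models import ModelSpec, make_estimator, rmse

logger = logging.getLogger(__name__)

DEFAULT_CRITERION = 0.01  # m/s of CV-RMSE improvement required per step
DEFAULT_K = 5
DEFAULT_MAX_FEATURES = 30


@dataclass
class SelectionResult:
    ordered_features: list[str]
    rmse_trajectory: list[float]
    wrapper_model: ModelSpec
    k_folds: int
    criterion: float = DEFAULT_CRITERION
    baseline_rmse: float = float("nan")
    empty: bool = False
    cap_hit: bool = False

    def __post_init__(self) -> None:
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise ValueError("duplicate features in selection")
        traj = [self.baseline_rmse] + self.rmse_trajectory
        for a, b in zip(traj, traj[1:]):
            if not (a - b > 0):
                raise ValueError("rmse_trajectory must be strictly decreasing")

    def to_dict(self) -> dict:
        return {
            "ordered_features": self.ordered_features,
            "rmse_trajectory": self.rmse_trajectory,
            "baseline_rmse": self.baseline_rmse,
            "wrapper": self.wrapper_model.to_dict(),
            "k_folds": self.k_folds,
            "criterion": self.criterion,
            "empty": self.empty,
            "cap_hit": self.cap_hit,
        }


def cv_rmse(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
            estimator, k: int) -> float:
    """Pooled k-fold (grouped) cross-validated RMSE of one feature subset."""
    cv = GroupKFold(n_splits=k)
    pred = np.empty_like(y, dtype=float)
    for train, test in cv.split(X, y, groups):
        est = clone(estimator)
        est.fit(X[train], y[train])
        pred[test] = est.predict(X[test])
    return rmse(pred, y)


def sffs_select(
    matrix: pd.DataFrame,
    wrapper: ModelSpec | None = None,
    k: int = DEFAULT_K,
    criterion: float = DEFAULT_CRITERION,
    seed: int = 0,
    max_features: int = DEFAULT_MAX_FEATURES,
    candidate_columns: list[str] | None = None,
) -> SelectionResult:
    """Run SFFS on a feature matrix (metadata columns are recognized by name).

    The wrapper defaults to a small random forest, the same family later
    trained, kept deliberately small: during selection only the *ranking* of
    subsets matters.
    """
    wrapper = wrapper or ModelSpec.wrapper_default(seed)
    cols = candidate_columns or feature_columns(matrix)
    if len(cols) < 2:
        raise ValueError("need at least 2 candidate features")
    y = matrix["speed"].to_numpy(dtype=float)
    if np.std(y) == 0.0:
        raise ValueError("constant target speed")
    groups = matrix["subject"].to_numpy()
    n_subjects = len(np.unique(groups))
    if k > n_subjects:
        raise ValueError(f"k = {k} exceeds number of subjects ({n_subjects})")
    if len(matrix) < 2 * k:
        raise ValueError("too few rows for k-fold selection")

    Xall = matrix[cols].to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(cols)}
    estimator = make_estimator(wrapper)

    cache: dict[frozenset, float] = {}

    def score(subset: tuple[str, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            idx = [col_index[c] for c in subset]
            cache[key] = cv_rmse(Xall[:, idx], y, groups, estimator, k)
        return cache[key]

    # predict-the-mean baseline: RMSE with no features
    baseline = float(np.sqrt(np.mean((y - y.mean()) ** 2)))

    selected: list[str] = []
    trajectory: list[float] = []
    current = baseline
    cap_hit = False

    while True:
        if len(selected) >= max_features:
            cap_hit = True
            logger.info("SFFS feature cap (%d) reached", max_features)
            break
        # forward step: best single addition (ties -> lowest column index)
        best_add, best_rmse = None, np.inf
        for c in cols:
            if c in selected:
                continue
            r = score(tuple(selected) + (c,))
            if r < best_rmse - 1e-12:
                best_add, best_rmse = c, r
        if best_add is None or current - best_rmse <= criterion:
            break
        selected.append(best_add)
        trajectory.append(best_rmse)
        current = best_rmse
        logger.debug("SFFS + %s -> RMSE %.4f", best_add, current)

        # floating step: conditional exclusions
        while len(selected) > 1:
            best_rm, best_rm_rmse = None, np.inf
            for c in selected:
                rest = tuple(f for f in selected if f != c)
                r = score(rest)
                if r < best_rm_rmse - 1e-12:
                    best_rm, best_rm_rmse = c, r
            if best_rm is not None and current - best_rm_rmse > criterion:
                selected.remove(best_rm)
                # trajectory records the accepted-state RMSE sequence
                trajectory.append(best_rm_rmse)
                current = best_rm_rmse
                logger.debug("SFFS - %s -> RMSE %.4f", best_rm, current)
            else:
                break

    return SelectionResult(
        ordered_features=selected,
        rmse_trajectory=trajectory,
        wrapper_model=wrapper,
        k_folds=k,
        criterion=criterion,
        baseline_rmse=baseline,
        empty=not selected,
        cap_hit=cap_hit,
    )


def exhaustive_best_subset(matrix: pd.DataFrame, wrapper: ModelSpec,
                           k: int = DEFAULT_K,
                           candidate_columns: list[str] | None = None,
                           ) -> tuple[tuple[str, ...], float]:
    """Brute-force search over all non-empty subsets; oracle for small p."""
    from itertools import combinations

    cols = candidate_columns or feature_columns(matrix)
    if len(cols) > 12:
        raise ValueError("exhaustive search is intended for small feature counts")
    y = matrix["speed"].to_numpy(dtype=float)
    groups = matrix["subject"].to_numpy()
    Xall = matrix[cols].to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(cols)}
    estimator = make_estimator(wrapper)

    best, best_rmse = None, np.inf
    for size in range(1, len(cols) + 1):
        for subset in combinations(cols, size):
            idx = [col_index[c] for c in subset]
            r = cv_rmse(Xall[:, idx], y, groups, estimator, k)
            if r < best_rmse:
                best, best_rmse = subset, r
    return best, best_rmse


def audit_floating_optimality(matrix: pd.DataFrame, result: SelectionResult,
                              ) -> bool:
    """Post-hoc check: no selected feature's removal improves CV RMSE by more
    than the criterion."""
    if len(result.ordered_features) <= 1:
        return True
    y = matrix["speed"].to_numpy(dtype=float)
    groups = matrix["subject"].to_numpy()
    estimator = make_estimator(result.wrapper_model)
    full_idx = result.ordered_features
    Xfull = matrix[full_idx].to_numpy(dtype=float)
    current = cv_rmse(Xfull, y, groups, estimator, result.k_folds)
    for c in result.ordered_features:
        rest = [f for f in result.ordered_features if f != c]
        r = cv_rmse(matrix[rest].to_numpy(dtype=float), y, groups,
                    estimator, result.k_folds)
        if current - r > result.criterion:
            return False
    return True
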