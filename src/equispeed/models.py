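"""Regression model families, LOSO cross-validation and evaluation metrics.

Five regressor families are compared: support-vector machine (SVM),
decision tree (DT), random forest (RF), boosted trees (BT; least-squares
gradient boosting) and Gaussian process regression (GPR).  Models are
evaluated with leave-one-subject-out (LOSO) cross-validation: each subject's
windows form one held-out fold, the model is refit on the remaining
subjects, and the per-fold predictions are pooled into a single prediction
vector before computing

    MAE   = mean |estimated - measured|            (m/s)
    RMSE  = sqrt(mean (estimated - measured)^2)    (m/s)
    nRMSE = RMSE / mean(measured) * 100            (%)

Per-gait rows apply the same formulas to the pooled predictions grouped by
the window's gait label.  The full experiment grid crosses the 11 feature
sets with the 5 families (55 cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .features import FEATURE_SETS, feature_columns

logger = logging.getLogger(__name__)

FAMILIES = ("SVM", "DT", "RF", "BT", "GPR")

#: fixed default hyperparameters per family
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "SVM": {"C": 10.0, "epsilon": 0.1, "gamma": "scale"},
    "DT": {"min_samples_leaf": 5},
    # regression-forest convention: mtry = p/3 (Breiman's regression default)
    "RF": {"n_estimators": 60, "max_features": 0.333, "min_samples_leaf": 2},
    "BT": {"n_estimators": 150, "learning_rate": 0.1, "max_depth": 3},
    "GPR": {"max_train": 800, "alpha": 1e-6},
}

#: small tuning grids for the optional inner grouped 3-fold search
TUNING_GRIDS: dict[str, dict] = {
    "SVM": {"svr__C": [1.0, 10.0, 100.0]},
    "DT": {"min_samples_leaf": [2, 5, 10]},
    "RF": {"max_features": ["sqrt", 0.3]},
    "BT": {"learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
    "GPR": {},  # kernel hyperparameters are optimized by marginal likelihood
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")

    def resolved_hyperparameters(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.family])
        hp.update(self.hyperparameters)
        return hp

    def to_dict(self) -> dict:
        return {"family": self.family,
                "hyperparameters": self.resolved_hyperparameters(),
                "seed": self.seed}

    @staticmethod
    def wrapper_default(seed: int = 0) -> "ModelSpec":
        """Small random forest used as the SFFS wrapper (ranking, not
        final accuracy, is what matters during selection)."""
        return ModelSpec("RF", {"n_estimators": 25, "max_depth": 10,
                                "max_features": 1.0}, seed=seed)


class _SubsampledRegressor:
    """Wrap an estimator so fitting uses at most ``max_train`` seeded rows.

    Used for GPR, whose exact fit is cubic in the training size.
    """

    def __init__(self, base, max_train: int, seed: int):
        self.base = base
        self.max_train = max_train
        self.seed = seed

    def get_params(self, deep: bool = False) -> dict:
        return {"base": self.base, "max_train": self.max_train, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        from sklearn.base import clone
        est = clone(self.base)
        n = len(y)
        if n > self.max_train:
            idx = np.random.default_rng(self.seed).choice(n, self.max_train, replace=False)
            X, y = X[idx], np.asarray(y)[idx]
        self.fitted_ = est.fit(X, y)
        return self

    def predict(self, X):
        return self.fitted_.predict(X)


def make_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator for a model spec."""
    hp = spec.resolved_hyperparameters()
    if spec.family == "SVM":
        return Pipeline([("scale", StandardScaler()),
                         ("svr", SVR(kernel="rbf", **hp))])
    if spec.family == "DT":
        return DecisionTreeRegressor(random_state=spec.seed, **hp)
    if spec.family == "RF":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **hp)
    if spec.family == "BT":
        return GradientBoostingRegressor(random_state=spec.seed, **hp)
    if spec.family == "GPR":
        hp = dict(hp)
        max_train = hp.pop("max_train")
        kernel = ConstantKernel(1.0) * RBF(length_scale=1.0) + WhiteKernel(0.1)
        gpr = Pipeline([("scale", StandardScaler()),
                        ("gpr", GaussianProcessRegressor(
                            kernel=kernel, normalize_y=True,
                            random_state=spec.seed, **hp))])
        return _SubsampledRegressor(gpr, max_train=max_train, seed=spec.seed)
    raise AssertionError(spec.family)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mae(estimated: np.ndarray, measured: np.ndarray) -> float:
    """Mean absolute error, m/s."""
    est, meas = _paired(estimated, measured)
    return float(np.mean(np.abs(est - meas)))


def rmse(estimated: np.ndarray, measured: np.ndarray) -> float:
    """Root-mean-square error, m/s."""
    est, meas = _paired(estimated, measured)
    return float(np.sqrt(np.mean((est - meas) ** 2)))


def nrmse(rmse_value: float, measured: np.ndarray) -> float:
    """RMSE normalized by the mean measured speed, in percent."""
    meas = np.asarray(measured, dtype=float)
    m = meas.mean()
    if m <= 0:
        raise ValueError("nRMSE undefined for non-positive mean measured speed")
    return float(rmse_value / m * 100.0)


def _paired(est, meas) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if est.shape != meas.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {meas.shape}")
    if est.size < 1:
        raise ValueError("need at least one prediction pair")
    return est, meas


# ---------------------------------------------------------------------------
# LOSO evaluation
# ---------------------------------------------------------------------------

@dataclass
class GaitMetrics:
    gait: str
    n: int
    mean_speed: float  # m/s, measured
    rmse: float        # m/s
    nrmse: float       # %


@dataclass
class EvaluationReport:
    feature_set: str
    family: str
    mae: float
    rmse: float
    nrmse: float
    per_gait: list[GaitMetrics]
    predictions: pd.DataFrame  # columns: subject, gait, measured, estimated
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    failed: bool = False
    error: str = ""

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "family": self.family,
            "mae": self.mae,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "per_gait": [vars(g) for g in self.per_gait],
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "failed": self.failed,
            "error": self.error,
        }


def _per_gait(pred: pd.DataFrame) -> list[GaitMetrics]:
    rows = []
    for gait, grp in pred.groupby("gait", sort=True):
        r = rmse(grp["estimated"].to_numpy(), grp["measured"].to_numpy())
        rows.append(GaitMetrics(gait=str(gait), n=len(grp),
                                mean_speed=float(grp["measured"].mean()),
                                rmse=r, nrmse=nrmse(r, grp["measured"].to_numpy())))
    return rows


def loso_cv(matrix: pd.DataFrame, selection=None, spec: ModelSpec | None = None,
            tune: bool = False, feature_set_name: str = "") -> EvaluationReport:
    """Leave-one-subject-out evaluation of one (feature set, family) cell.

    ``selection`` may be a SelectionResult, an explicit column list, or None
    (all feature columns).  With ``tune=True`` each fold runs an inner
    subject-grouped 3-fold grid search over the family's small tuning grid.
    """
    spec = spec or ModelSpec("RF")
    if selection is None:
        cols = feature_columns(matrix)
    elif hasattr(selection, "ordered_features"):
        cols = list(selection.ordered_features)
    else:
        cols = list(selection)
    if not cols:
        raise ValueError("no features to train on")
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"selected features absent from matrix: {missing[:3]}")

    subjects = matrix["subject"].to_numpy()
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 subjects")

    X = matrix[cols].to_numpy(dtype=float)
    y = matrix["speed"].to_numpy(dtype=float)
    gaits = matrix["gait"].to_numpy()

    parts = []
    chosen_hp: dict = spec.resolved_hyperparameters()
    for subj in uniq:
        test = subjects == subj
        train = ~test
        if test.sum() == 0:
            logger.warning("subject %s has zero windows; dropped", subj)
            continue
        est = make_estimator(spec)
        if tune and TUNING_GRIDS[spec.family]:
            inner = GroupKFold(n_splits=min(3, len(np.unique(subjects[train]))))
            gs = GridSearchCV(est, TUNING_GRIDS[spec.family], cv=inner,
                              scoring="neg_root_mean_squared_error", n_jobs=1)
            gs.fit(X[train], y[train], groups=subjects[train])
            est = gs.best_estimator_
            chosen_hp = {**chosen_hp, **gs.best_params_}
        else:
            est.fit(X[train], y[train])
        pred = est.predict(X[test])
        parts.append(pd.DataFrame({"subject": subj, "gait": gaits[test],
                                   "measured": y[test], "estimated": pred}))

    pooled = pd.concat(parts, ignore_index=True)
    r = rmse(pooled["estimated"].to_numpy(), pooled["measured"].to_numpy())
    return EvaluationReport(
        feature_set=feature_set_name,
        family=spec.family,
        mae=mae(pooled["estimated"].to_numpy(), pooled["measured"].to_numpy()),
        rmse=r,
        nrmse=nrmse(r, pooled["measured"].to_numpy()),
        per_gait=_per_gait(pooled),
        predictions=pooled,
        hyperparameters=chosen_hp,
        seed=spec.seed,
    )


def mean_baseline_loso(matrix: pd.DataFrame) -> float:
    """Pooled LOSO RMSE of predicting the training-fold mean speed."""
    subjects = matrix["subject"].to_numpy()
    y = matrix["speed"].to_numpy(dtype=float)
    pred = np.empty_like(y)
    for subj in np.unique(subjects):
        test = subjects == subj
        pred[test] = y[~test].mean()
    return rmse(pred, y)


def run_grid(feature_matrices: dict[str, pd.DataFrame],
             families: tuple[str, ...] = FAMILIES,
             selections: dict | None = None,
             seed: int = 0, tune: bool = False,
             ) -> tuple[pd.DataFrame, dict[tuple[str, str], EvaluationReport]]:
    """Evaluate every (feature set x family) cell.

    ``feature_matrices`` maps feature-set name -> matrix (normally the 11
    sets); ``selections`` optionally maps set name -> SelectionResult or
    column list.  Returns a wide results table (rows = feature sets, MAE and
    RMSE columns per family) plus the individual reports.  A failed cell is
    recorded and the grid still emitted.
    """
    reports: dict[tuple[str, str], EvaluationReport] = {}
    for set_name, matrix in feature_matrices.items():
        sel = (selections or {}).get(set_name)
        for family in families:
            spec = ModelSpec(family, seed=seed)
            try:
                rep = loso_cv(matrix, selection=sel, spec=spec, tune=tune,
                              feature_set_name=set_name)
            except Exception as exc:  # noqa: BLE001 - cell isolation
                logger.error("grid cell (%s, %s) failed: %s", set_name, family, exc)
                rep = EvaluationReport(feature_set=set_name, family=family,
                                       mae=np.nan, rmse=np.nan, nrmse=np.nan,
                                       per_gait=[], predictions=pd.DataFrame(),
                                       failed=True, error=str(exc), seed=seed)
            reports[(set_name, family)] = rep

    rows = []
    for set_name in feature_matrices:
        row: dict = {"feature_set": set_name}
        for family in families:
            rep = reports[(set_name, family)]
            row[f"{family}_MAE"] = rep.mae
            row[f"{family}_RMSE"] = rep.rmse
        rows.append(row)
    return pd.DataFrame(rows), reports


def grid_feature_matrices(windows, sets: tuple[str, ...] | None = None,
                          ) -> dict[str, pd.DataFrame]:
    """Build the feature matrix of every named feature set from one window list.

    Features are computed once over all locations and sliced per set, so
    the 11 sets cost one extraction pass.
    """
    from .features import (CHANNELS, FEATURE_NAMES, METADATA_COLUMNS,
                           build_feature_matrix, feature_column)
    sets = sets or tuple(FEATURE_SETS)
    all_locs = sorted({loc for name in sets for loc in FEATURE_SETS[name].locations},
                      key=lambda l: FEATURE_SETS["All"].locations.index(l))
    base = build_feature_matrix(windows, type(FEATURE_SETS["All"])("_union", tuple(all_locs)))
    out = {}
    for name in sets:
        cols = list(METADATA_COLUMNS) + [
            feature_column(f, ch, loc)
            for loc in FEATURE_SETS[name].locations
            for ch in CHANNELS for f in FEATURE_NAMES]
        out[name] = base[cols]
    return out
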