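"""Fatigue-level regression: estimator, baseline, RFE, holdout and LOSO.

The central object is :class:`FatigueRegressor`, a scikit-learn style
estimator that grid-searches one of four regressor families (random
forest, PLS, bagged SVR, AdaBoost on regression trees) under repeated
5-fold cross-validation scored by mean absolute error, after normalising
every sample vector to unit Euclidean length.  Module-level functions are
thin wrappers for pipeline scripting.  Chance performance comes from a
Monte-Carlo baseline drawing predictions i.i.d. from the empirical label
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    AdaBoostRegressor,
    BaggingRegressor,
    RandomForestRegressor,
)
from sklearn.inspection import permutation_importance
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    LeaveOneGroupOut,
    RepeatedKFold,
    cross_val_predict,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import Normalizer
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: 5x5 repeated CV and an 80/20 holdout."""

    n_folds: int = 5
    n_repeats: int = 5
    holdout_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need >= 2 folds")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction must be in (0, 1)")


#: Default hyperparameter grids (package defaults, configurable).
DEFAULT_GRIDS = {
    "rfr": {
        "n_estimators": [100, 300],
        "max_depth": [None, 5, 10],
        "min_samples_leaf": [1, 5],
    },
    "pls": {"n_components": list(range(1, 9))},
    "svr": {
        "estimator__C": [0.1, 1.0, 10.0],
        "estimator__epsilon": [0.01, 0.1],
    },
    "rt": {"n_estimators": [50, 200], "learning_rate": [0.1, 1.0]},
}

MODEL_NAMES = tuple(DEFAULT_GRIDS)


def _base_estimator(model: str, seed: int):
    if model == "rfr":
        return RandomForestRegressor(random_state=seed)
    if model == "pls":
        return PLSRegression()
    if model == "svr":
        return BaggingRegressor(SVR(), n_estimators=10, random_state=seed)
    if model == "rt":
        return AdaBoostRegressor(DecisionTreeRegressor(max_depth=4), random_state=seed)
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


class FatigueRegressor(RegressorMixin, BaseEstimator):
    """Grid-searched fatigue-level regressor with row normalisation.

    Parameters
    ----------
    model : {"rfr", "pls", "svr", "rt"}
        Regressor family: random forest, partial least squares, bagged
        support-vector regression, or AdaBoost with regression trees.
    grid : dict or None
        Hyperparameter grid for the family; ``None`` uses
        :data:`DEFAULT_GRIDS`.
    n_folds, n_repeats : int
        Repeated k-fold layout of the model-selection CV.
    normalize : bool
        Scale each sample vector to unit Euclidean length before fitting.
    random_state : int
        Seed for CV shuffling and stochastic estimators.

    Attributes
    ----------
    best_params_ : dict
        Winning hyperparameters (pipeline-prefixed keys stripped).
    cv_mae_ : float
        Mean CV mean-absolute-error of the winning configuration.
    explained_variance_ : float
        ``1 - Var(y - yhat) / Var(y)`` on out-of-fold CV predictions, %.
    estimator_ : Pipeline
        The refit winning pipeline.
    """

    def __init__(
        self,
        model: str = "rfr",
        grid: dict | None = None,
        n_folds: int = 5,
        n_repeats: int = 5,
        normalize: bool = True,
        random_state: int = 0,
    ):
        self.model = model
        self.grid = grid
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.normalize = normalize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2 * self.n_folds)
        base = _base_estimator(self.model, self.random_state)
        steps = ([("norm", Normalizer())] if self.normalize else []) + [("est", base)]
        pipe = Pipeline(steps)
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.model]
        grid = {f"est__{k}": v for k, v in grid.items()}
        cv = RepeatedKFold(
            n_splits=self.n_folds,
            n_repeats=self.n_repeats,
            random_state=self.random_state,
        )
        search = GridSearchCV(
            pipe, grid, scoring="neg_mean_absolute_error", cv=cv, refit=True
        )
        search.fit(X, y)
        self.best_params_ = {
            k.removeprefix("est__"): v for k, v in search.best_params_.items()
        }
        self.cv_mae_ = float(-search.best_score_)
        self.estimator_ = search.best_estimator_
        yhat = cross_val_predict(
            clone(search.best_estimator_),
            X,
            y,
            cv=KFold(self.n_folds, shuffle=True, random_state=self.random_state),
        ).ravel()
        var_y = float(np.var(y))
        if var_y == 0:
            warnings.warn("constant labels: explained variance undefined, set to 0")
            self.explained_variance_ = 0.0
        else:
            self.explained_variance_ = float(
                100.0 * (1.0 - np.var(np.asarray(y) - yhat) / var_y)
            )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.asarray(self.estimator_.predict(X)).ravel()

    def feature_importances(self, X=None, y=None, seed: int = 0) -> np.ndarray:
        """Importance per input feature: impurity-based for tree models
        (sums to 1), permutation-based otherwise (requires X, y)."""
        check_is_fitted(self)
        est = self.estimator_.named_steps["est"]
        if hasattr(est, "feature_importances_"):
            return np.asarray(est.feature_importances_)
        if X is None or y is None:
            raise ValueError("permutation importance requires X and y")
        res = permutation_importance(
            self.estimator_, X, y, n_repeats=10, random_state=seed,
            scoring="neg_mean_absolute_error",
        )
        return res.importances_mean


# ---------------------------------------------------------------------------
# module-level operations


def normalize_rows(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Scale every row to unit Euclidean length (zero rows stay zero)."""
    arr = np.asarray(X, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values in feature matrix")
    zero = np.linalg.norm(arr, axis=1) == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero row(s) left unnormalised")
    return Normalizer().fit_transform(arr)


def monte_carlo_baseline_mae(
    distribution: dict | pd.Series,
    observed: np.ndarray,
    n_sim: int = 10_000,
    seed: int = 0,
    score_against: str = "observed",
) -> tuple[float, float]:
    """Chance-level MAE from a label-distribution random predictor.

    Predictions are drawn i.i.d. from ``distribution`` (level -> mass) and
    scored by MAE against the observed labels (or, with
    ``score_against="simulated"``, against an independent draw from the
    same distribution), averaged over ``n_sim`` replicates.

    Returns ``(baseline_mae, standard_error)``.
    """
    if isinstance(distribution, pd.Series):
        distribution = distribution.to_dict()
    if not distribution:
        raise ValueError("empty label distribution")
    levels = np.array(sorted(distribution))
    p = np.array([distribution[l] for l in levels], dtype=float)
    if p.sum() <= 0:
        raise ValueError("distribution has no mass")
    p = p / p.sum()
    obs = np.asarray(observed, dtype=float)
    rng = np.random.default_rng(seed)
    sims = levels[rng.choice(len(levels), size=(n_sim, len(obs)), p=p)]
    if score_against == "simulated":
        target = levels[rng.choice(len(levels), size=(n_sim, len(obs)), p=p)]
    else:
        target = obs[None, :]
    maes = np.abs(sims - target).mean(axis=1)
    return float(maes.mean()), float(maes.std(ddof=1) / np.sqrt(n_sim))


def empirical_label_distribution(labels: np.ndarray) -> dict:
    """Observed relative frequency of each label level."""
    vals, counts = np.unique(np.asarray(labels), return_counts=True)
    return {float(v): c / counts.sum() for v, c in zip(vals, counts)}


def crossval_grid_search(
    X, y, model: str = "rfr", cv: CVSpec = CVSpec(), grid: dict | None = None
) -> FatigueRegressor:
    """Fit a :class:`FatigueRegressor` under the given CV layout."""
    reg = FatigueRegressor(
        model=model,
        grid=grid,
        n_folds=cv.n_folds,
        n_repeats=cv.n_repeats,
        random_state=cv.seed,
    )
    return reg.fit(X, y)


def rfe_select(
    X: pd.DataFrame,
    y,
    model: str = "rfr",
    cv: CVSpec = CVSpec(),
    grid: dict | None = None,
    n_repeats_step: int = 1,
) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination: drop one feature per step.

    At each step the current subset is scored by repeated-CV MAE and the
    least important feature (per the model fitted on the whole subset) is
    dropped.  Returns the subset minimising CV MAE and the full curve.
    ``n_repeats_step`` keeps the per-step CV cheap; the winning subset
    should be re-scored with the full CVSpec by the caller if needed.
    """
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    current = list(X.columns)
    curve = []
    best = (np.inf, current)
    while current:
        Xc = X[current].to_numpy()
        # per-step grid search would be quadratic in cost; the elimination
        # loop uses the family's default hyperparameters throughout
        base = _base_estimator(model, cv.seed)
        if grid:
            base.set_params(**{k: v[0] for k, v in grid.items() if len(v) == 1})
        pipe = Pipeline([("norm", Normalizer()), ("est", base)])
        scores = cross_val_score(
            pipe,
            Xc,
            y,
            scoring="neg_mean_absolute_error",
            cv=RepeatedKFold(
                n_splits=cv.n_folds, n_repeats=n_repeats_step, random_state=cv.seed
            ),
        )
        mae = float(-scores.mean())
        curve.append({"n_features": len(current), "features": list(current), "cv_mae": mae})
        if mae < best[0]:
            best = (mae, list(current))
        if len(current) == 1:
            break
        pipe.fit(Xc, y)
        est = pipe.named_steps["est"]
        if hasattr(est, "feature_importances_"):
            imp = np.asarray(est.feature_importances_)
        else:
            imp = permutation_importance(
                pipe, Xc, y, n_repeats=5, random_state=cv.seed,
                scoring="neg_mean_absolute_error",
            ).importances_mean
        current.pop(int(np.argmin(imp)))
    return best[1], pd.DataFrame(curve)


def holdout_evaluate(
    X, y, model: str = "rfr", cv: CVSpec = CVSpec(), grid: dict | None = None
) -> tuple[float, FatigueRegressor]:
    """Stratified 80/20 split; grid-search on the 80%, MAE on the 20%."""
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    Xtr, Xte, ytr, yte = train_test_split(
        X,
        y,
        test_size=cv.holdout_fraction,
        random_state=cv.seed,
        stratify=y,
    )
    reg = crossval_grid_search(Xtr, ytr, model=model, cv=cv, grid=grid)
    mae = float(mean_absolute_error(yte, reg.predict(Xte)))
    return mae, reg


def loso_evaluate(
    X,
    y,
    groups,
    model: str = "rfr",
    cv: CVSpec = CVSpec(),
    grid: dict | None = None,
) -> tuple[pd.Series, dict]:
    """Leave-one-subject-out: train on all others, test on the held-out one.

    Returns the per-subject MAE series and a min/mean/max summary.  The
    per-fold model uses the family's default grid search on the training
    subjects only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 3:
        raise ValueError("need >= 3 subjects for LOSO")
    out = {}
    logo = LeaveOneGroupOut()
    for tr, te in logo.split(X, y, groups):
        subj = groups[te][0]
        if len(te) == 0:
            warnings.warn(f"subject {subj} has no rows; skipped")
            continue
        reg = crossval_grid_search(X[tr], y[tr], model=model, cv=cv, grid=grid)
        out[subj] = float(mean_absolute_error(y[te], reg.predict(X[te])))
    s = pd.Series(out, name="loso_mae").sort_index()
    summary = {
        "min": float(s.min()),
        "mean": float(s.mean()),
        "max": float(s.max()),
        "n_subjects": int(len(s)),
    }
    return s, summary


def feature_importances(
    reg: FatigueRegressor, feature_names: list[str], X=None, y=None
) -> pd.Series:
    """Descending importance ranking of the fitted model's inputs."""
    imp = reg.feature_importances(X, y)
    return pd.Series(imp, index=feature_names).sort_values(ascending=False)
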