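"""Predictive models: single-variable linear fits and random forests over
six variable strategies.

Strategy names follow the chemometric shorthand used throughout the
package: ``1DV`` are the five retained PCA scores, ``2DI`` the five
optimal two-band index values, ``3DI`` the five optimal three-band index
values, and the pairwise unions (``1DV+2DI`` etc.) stack ten columns.

Random forests use 1000 bagged regression trees by default with the
common regression node size of 5; ``m_try`` (features tried per split) is
tuned by minimising the out-of-bag RMSE on the calibration set — OOB
rather than resubstitution, since resubstitution RMSE is nearly monotone
in ``m_try`` and would make the tuning vacuous.  Variable importances are
impurity-based and normalised to sum to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from sklearn.ensemble import RandomForestRegressor

from . import metrics as _metrics

__all__ = [
    "FeatureSet",
    "ModelResult",
    "STRATEGIES",
    "fit_linear",
    "tune_mtry",
    "fit_rf",
    "normalize_importance",
    "build_feature_sets",
    "run_all_strategies",
]

STRATEGIES = ("1DV", "2DI", "3DI", "1DV+2DI", "1DV+3DI", "2DI+3DI")


@dataclass
class FeatureSet:
    """Named feature columns for calibration and validation."""

    name: str
    feature_names: list
    X_cal: np.ndarray
    X_val: np.ndarray

    def __post_init__(self):
        self.X_cal = np.atleast_2d(np.asarray(self.X_cal, dtype=float))
        self.X_val = np.atleast_2d(np.asarray(self.X_val, dtype=float))
        if self.X_cal.shape[1] != self.X_val.shape[1]:
            raise ValueError("calibration and validation must share columns")
        if self.X_cal.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if not (np.all(np.isfinite(self.X_cal)) and np.all(np.isfinite(self.X_val))):
            raise ValueError("features contain missing or non-finite values")

    @property
    def n_features(self) -> int:
        return self.X_cal.shape[1]


@dataclass
class ModelResult:
    strategy: str
    model_kind: str                # "linear" | "random_forest"
    hyperparameters: dict
    pred_cal: np.ndarray
    pred_val: np.ndarray
    metrics: "_metrics.Metrics"
    importance: dict = field(default_factory=dict)  # feature -> % (RF only)


def fit_linear(x, y):
    """Ordinary least squares of y on a single feature.

    Returns ``(slope, intercept, predictions)`` where predictions are the
    fitted values on ``x``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("feature is constant; OLS undefined")
    res = _stats.linregress(x, y)
    return float(res.slope), float(res.intercept), res.slope * x + res.intercept


def _drop_duplicate_columns(X: np.ndarray, names: list):
    """Drop exact duplicate feature columns, keeping the first, with a warning."""
    keep = []
    for j in range(X.shape[1]):
        dup = any(np.array_equal(X[:, j], X[:, i]) for i in keep)
        if dup:
            warnings.warn(f"dropping duplicate feature column {names[j]!r}", stacklevel=3)
        else:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep], keep


def fit_rf(
    X,
    y,
    m_try: int,
    n_trees: int = 1000,
    nodesize: int = 5,
    seed: int = 0,
    oob: bool = False,
) -> RandomForestRegressor:
    """Bagged regression-tree ensemble (random forest) with fixed seed."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 10:
        raise ValueError("random forest needs at least 10 samples")
    if not 1 <= m_try <= X.shape[1]:
        raise ValueError(f"m_try must be in [1, {X.shape[1]}]")
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=m_try,
        min_samples_leaf=nodesize,
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        rf.fit(X, y)
    return rf


def _oob_rmse(rf: RandomForestRegressor, y: np.ndarray) -> float:
    # samples never left out of bag (rare at n_trees >= 100) are excluded
    pred = rf.oob_prediction_
    ok = np.isfinite(pred)
    return _metrics.rmse(y[ok], pred[ok])


def tune_mtry(X, y, mtry_range, n_trees: int = 1000, nodesize: int = 5, seed: int = 0) -> int:
    """Select m_try by minimum out-of-bag RMSE; ties go to the smaller value."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    mtry_range = list(mtry_range)
    if not mtry_range:
        raise ValueError("empty m_try range")
    if max(mtry_range) > X.shape[1] or min(mtry_range) < 1:
        raise ValueError("m_try range outside [1, n_features]")
    best, best_rmse = None, np.inf
    for m in mtry_range:
        rf = fit_rf(X, y, m_try=m, n_trees=n_trees, nodesize=nodesize, seed=seed, oob=True)
        r = _oob_rmse(rf, y)
        if r < best_rmse:
            best, best_rmse = m, r
    return int(best)


def normalize_importance(raw) -> np.ndarray:
    """Rescale non-negative raw importances to percentages summing to 100."""
    raw = np.asarray(raw, dtype=float).ravel()
    if np.any(raw < 0):
        raise ValueError("raw importances must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("all-zero importances cannot be normalized")
    return 100.0 * raw / total


def build_feature_sets(
    pca_scores_cal: np.ndarray,
    pca_scores_val: np.ndarray,
    two_band_cal: dict,
    two_band_val: dict,
    three_band_cal: dict,
    three_band_val: dict,
) -> dict:
    """Assemble the six strategy FeatureSets from PCA scores and index values.

    ``two_band_cal`` etc. map index-form names to per-sample value vectors.
    Exact duplicate columns within a strategy are dropped with a warning.
    """
    pc_names = [f"PC{i + 1}" for i in range(pca_scores_cal.shape[1])]
    blocks = {
        "1DV": (pc_names, pca_scores_cal, pca_scores_val),
        "2DI": (
            list(two_band_cal),
            np.column_stack(list(two_band_cal.values())),
            np.column_stack(list(two_band_val.values())),
        ),
        "3DI": (
            list(three_band_cal),
            np.column_stack(list(three_band_cal.values())),
            np.column_stack(list(three_band_val.values())),
        ),
    }
    sets = {}
    for name in STRATEGIES:
        parts = name.split("+")
        names = sum((blocks[p][0] for p in parts), [])
        Xc = np.column_stack([blocks[p][1] for p in parts])
        Xv = np.column_stack([blocks[p][2] for p in parts])
        Xc, kept_names, keep = _drop_duplicate_columns(Xc, names)
        Xv = Xv[:, keep]
        sets[name] = FeatureSet(name=name, feature_names=kept_names, X_cal=Xc, X_val=Xv)
    return sets


def run_all_strategies(
    feature_sets: dict,
    y_cal: np.ndarray,
    y_val: np.ndarray,
    n_trees: int = 1000,
    nodesize: int = 5,
    seed: int = 0,
    strategies=STRATEGIES,
) -> list:
    """Tune, fit and evaluate a random forest for each requested strategy.

    Single-block strategies tune m_try over 1..5, pairwise ones over
    1..10 (capped at the number of features).  Returns one ModelResult
    per strategy, in canonical order.
    """
    results = []
    for name in strategies:
        fs = feature_sets[name]
        hi = 5 if "+" not in name else 10
        mtry_range = range(1, min(hi, fs.n_features) + 1)
        m = tune_mtry(fs.X_cal, y_cal, mtry_range, n_trees=n_trees, nodesize=nodesize, seed=seed)
        rf = fit_rf(fs.X_cal, y_cal, m_try=m, n_trees=n_trees, nodesize=nodesize, seed=seed)
        pred_cal = rf.predict(fs.X_cal)
        pred_val = rf.predict(fs.X_val)
        imp = normalize_importance(rf.feature_importances_)
        results.append(
            ModelResult(
                strategy=name,
                model_kind="random_forest",
                hyperparameters={"n_trees": n_trees, "m_try": m, "nodesize": nodesize},
                pred_cal=pred_cal,
                pred_val=pred_val,
                metrics=_metrics.evaluate(y_cal, pred_cal, y_val, pred_val),
                importance=dict(zip(fs.feature_names, imp)),
            )
        )
    return results
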