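"""Chemometric accuracy metrics: R², RMSE, RPIQ with quality categories,
ANOVA stability check and confidence/prediction bands for 1:1 plots.

RPIQ (ratio of performance to interquartile distance) is the interquartile
range of the *observed validation* values divided by the validation RMSE.
It is preferred over RPD for skewed soil properties because the IQR is
robust to the heavy tail.  Model quality categories:

===========  =====================  ========================
A            RPIQ > 4.05            excellent predictability
B            3.37 < RPIQ <= 4.05    good
C            2.70 < RPIQ <= 3.37    limited
D            RPIQ <= 2.70           poor
===========  =====================  ========================

Boundary values close downward into the lower category (the defining
inequalities are strict, so exact boundaries need a convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .partition import anova_p

__all__ = [
    "Metrics",
    "r_squared",
    "r_squared_ss",
    "rmse",
    "rpiq",
    "rpiq_from_iqr",
    "rpiq_category",
    "interval_bands",
    "stability_anova",
    "evaluate",
]


@dataclass
class Metrics:
    r2_cal: float
    rmse_cal: float   # g kg^-1
    r2_val: float
    rmse_val: float   # g kg^-1
    rpiq: float
    category: str


def r_squared(obs, pred) -> float:
    """Squared Pearson correlation between observed and predicted values.

    The chemometric convention: affine-invariant, symmetric in its
    arguments.  A constant prediction vector has no correlation and
    returns 0 with a warning.  For the sum-of-squares definition see
    :func:`r_squared_ss`.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("length mismatch")
    if obs.size < 3:
        raise ValueError("need at least 3 points")
    oc = obs - obs.mean()
    so = float(oc @ oc)
    if so == 0:
        raise ValueError("observed values are constant")
    pc = pred - pred.mean()
    sp = float(pc @ pc)
    if sp == 0:
        warnings.warn("constant predictions: R^2 reported as 0", stacklevel=2)
        return 0.0
    r = float(oc @ pc) / np.sqrt(so * sp)
    return min(r * r, 1.0)


def r_squared_ss(obs, pred) -> float:
    """1 - SS_res / SS_tot (can be negative for poor models)."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0:
        raise ValueError("observed values are constant")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sstot


def rmse(obs, pred) -> float:
    """Root mean square error, in the units of the observations."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size == 0:
        raise ValueError("empty input")
    if obs.size != pred.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def rpiq(obs_val, rmse_val: float) -> float:
    """IQR of the observed validation values divided by validation RMSE."""
    obs_val = np.asarray(obs_val, dtype=float).ravel()
    if obs_val.size < 4:
        raise ValueError("need at least 4 validation observations for an IQR")
    q1, q3 = np.percentile(obs_val, [25, 75])
    return rpiq_from_iqr(q3 - q1, rmse_val)


def rpiq_from_iqr(iqr: float, rmse_val: float) -> float:
    """RPIQ from an already-computed IQR (e.g. a published table value)."""
    if rmse_val <= 0:
        raise ValueError("RPIQ undefined for non-positive RMSE")
    if iqr < 0:
        raise ValueError("IQR must be non-negative")
    return iqr / rmse_val


def rpiq_category(value: float) -> str:
    """Quality category A/B/C/D for an RPIQ value (A best)."""
    if value <= 0:
        raise ValueError("RPIQ must be positive")
    if value > 4.05:
        return "A"
    if value > 3.37:
        return "B"
    if value > 2.70:
        return "C"
    return "D"


def interval_bands(obs, pred, alpha: float = 0.05, grid: np.ndarray | None = None) -> dict:
    """95% confidence and prediction bands around the pred-vs-obs OLS line.

    Fits ``pred = a + b * obs`` by OLS and returns pointwise bands: the
    confidence band covers the mean response, the wider prediction band a
    new single observation.  Used to dress 1:1 scatter plots.

    Returns a dict with keys ``x``, ``fit``, ``conf_low``, ``conf_high``,
    ``pred_low``, ``pred_high``, ``slope``, ``intercept``.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("length mismatch")
    if obs.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(obs) == 0:
        raise ValueError("observed values are constant")
    if grid is None:
        grid = np.linspace(obs.min(), obs.max(), 100)
    grid = np.asarray(grid, dtype=float).ravel()
    X = np.column_stack([np.ones_like(obs), obs])
    fit = sm.OLS(pred, X).fit()
    Xg = np.column_stack([np.ones_like(grid), grid])
    frame = fit.get_prediction(Xg).summary_frame(alpha=alpha)
    return {
        "x": grid,
        "fit": frame["mean"].to_numpy(),
        "conf_low": frame["mean_ci_lower"].to_numpy(),
        "conf_high": frame["mean_ci_upper"].to_numpy(),
        "pred_low": frame["obs_ci_lower"].to_numpy(),
        "pred_high": frame["obs_ci_upper"].to_numpy(),
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
    }


def stability_anova(metric_cal, metric_val) -> float:
    """ANOVA p for calibration-vs-validation metric stability (reuses anova_p)."""
    return anova_p(metric_cal, metric_val)


def evaluate(obs_cal, pred_cal, obs_val, pred_val) -> Metrics:
    """Bundle the standard calibration/validation metric set."""
    rm_val = rmse(obs_val, pred_val)
    rp = rpiq(obs_val, rm_val)
    return Metrics(
        r2_cal=r_squared(obs_cal, pred_cal),
        rmse_cal=rmse(obs_cal, pred_cal),
        r2_val=r_squared(obs_val, pred_val),
        rmse_val=rm_val,
        rpiq=rp,
        category=rpiq_category(rp),
    )
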