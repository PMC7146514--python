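"""Table and figure export for a completed analysis.

Produces the conventional deliverables of a soil-spectroscopy modeling
study: a descriptive-statistics table, a linear-model summary per
spectral variable, a random-forest summary per strategy, normalised
variable-importance tables/plots, 1:1 scatter plots with 95% confidence
and prediction bands, a 2-D correlation contour per two-band form and
orthogonal slice panels per three-band form.  All outputs are
deterministic: rerunning with identical inputs rewrites byte-identical
CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .band_search import CorrelationMap, SelectedIndex, slice_views
from .metrics import interval_bands
from .models import ModelResult
from .partition import describe

__all__ = [
    "describe_table",
    "linear_summary_table",
    "rf_summary_table",
    "importance_table",
    "scatter_figure",
    "contour_figure",
    "slices_figure",
    "render_report",
]


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def describe_table(groups: dict) -> pd.DataFrame:
    """Descriptive statistics (one row per named value vector)."""
    rows = []
    for name, values in groups.items():
        d = describe(values)
        rows.append(
            {
                "data_set": name,
                "n": d.n,
                "min": _round2(d.min),
                "mean": _round2(d.mean),
                "max": _round2(d.max),
                "std": _round2(d.std),
                "iqr": _round2(d.iqr),
                "cv_percent": _round2(d.cv_percent),
                "skewness": _round2(d.skewness),
                "kurtosis": _round2(d.kurtosis),
            }
        )
    return pd.DataFrame(rows)


def linear_summary_table(rows: list) -> pd.DataFrame:
    """Summary of single-variable linear models.

    ``rows`` are dicts with keys: dimension, variable, slope, intercept,
    r2_cal, rmse_cal, r2_val, rmse_val, rpiq.
    """
    df = pd.DataFrame(rows)
    df["equation"] = [
        f"y = {r.intercept:.2f} {'+' if r.slope >= 0 else '-'} {abs(r.slope):.2f}x"
        for r in df.itertuples()
    ]
    for col in ("r2_cal", "rmse_cal", "r2_val", "rmse_val", "rpiq"):
        df[col] = df[col].round(2)
    cols = ["dimension", "variable", "equation", "r2_cal", "rmse_cal", "r2_val", "rmse_val", "rpiq"]
    return df[cols]


def rf_summary_table(results: list) -> pd.DataFrame:
    """Strategy-by-strategy random-forest summary."""
    rows = []
    for res in results:
        m = res.metrics
        rows.append(
            {
                "strategy": res.strategy,
                "m_try": res.hyperparameters["m_try"],
                "r2_cal": _round2(m.r2_cal),
                "rmse_cal": _round2(m.rmse_cal),
                "r2_val": _round2(m.r2_val),
                "rmse_val": _round2(m.rmse_val),
                "rpiq": _round2(m.rpiq),
                "category": m.category,
            }
        )
    return pd.DataFrame(rows)


def importance_table(result: ModelResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature": list(result.importance), "importance_percent": list(result.importance.values())}
    )


def scatter_figure(obs_cal, pred_cal, obs_val, pred_val, title: str = "") -> plt.Figure:
    """1:1 scatter of predicted vs observed SOM with 95% CI/PI bands."""
    fig, ax = plt.subplots(figsize=(5, 5))
    bands = interval_bands(np.concatenate([obs_cal, obs_val]), np.concatenate([pred_cal, pred_val]))
    ax.fill_between(bands["x"], bands["pred_low"], bands["pred_high"], color="salmon", alpha=0.35,
                    label="95% prediction band")
    ax.fill_between(bands["x"], bands["conf_low"], bands["conf_high"], color="crimson", alpha=0.45,
                    label="95% confidence band")
    ax.plot(bands["x"], bands["fit"], color="crimson", lw=1)
    ax.scatter(obs_cal, pred_cal, s=18, c="tab:blue", label="calibration")
    ax.scatter(obs_val, pred_val, s=18, c="tab:green", marker="^", label="validation")
    lims = [min(ax.get_xlim()[0], ax.get_ylim()[0]), max(ax.get_xlim()[1], ax.get_ylim()[1])]
    ax.plot(lims, lims, "k--", lw=0.8, label="1:1 line")
    ax.set_xlabel("Observed SOM (g kg$^{-1}$)")
    ax.set_ylabel("Predicted SOM (g kg$^{-1}$)")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def contour_figure(cmap: CorrelationMap, title: str = "") -> plt.Figure:
    """2-D image map of Pearson r over all two-band combinations."""
    if cmap.form.arity != 2:
        raise ValueError("contour_figure takes a two-band map")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(cmap.wavelengths, cmap.wavelengths, cmap.r.T, cmap="RdBu_r",
                       vmin=-1, vmax=1, shading="nearest")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xlabel("$\\lambda_i$ (nm)")
    ax.set_ylabel("$\\lambda_j$ (nm)")
    ax.set_title(title or cmap.form.name)
    fig.tight_layout()
    return fig


def slices_figure(cmap: CorrelationMap, best: SelectedIndex, title: str = "") -> plt.Figure:
    """Orthogonal slice panels of a three-band correlation cube."""
    views = slice_views(cmap, best)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    labels = {"x": ("$\\lambda_j$", "$\\lambda_k$"), "y": ("$\\lambda_i$", "$\\lambda_k$"),
              "z": ("$\\lambda_i$", "$\\lambda_j$")}
    for ax, (axis, plane) in zip(axes, views.planes.items()):
        im = ax.pcolormesh(cmap.wavelengths, cmap.wavelengths, plane.T, cmap="RdBu_r",
                           vmin=-1, vmax=1, shading="nearest")
        ax.set_xlabel(labels[axis][0] + " (nm)")
        ax.set_ylabel(labels[axis][1] + " (nm)")
        ax.set_title(f"{axis}-axis slice through optimum")
    fig.colorbar(im, ax=axes, label="Pearson r")
    fig.suptitle(title or cmap.form.name)
    return fig


def render_report(
    out_dir,
    describe_groups: dict | None = None,
    linear_rows: list | None = None,
    rf_results: list | None = None,
    selections: dict | None = None,
    y_cal=None,
    y_val=None,
    two_band_maps: dict | None = None,
    figures: bool = True,
) -> dict:
    """Write the available tables (CSV), metrics (JSON) and figures (PNG).

    Any argument left ``None`` is skipped; the returned dict maps artifact
    names to the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    if describe_groups:
        p = out_dir / "descriptive_statistics.csv"
        describe_table(describe_groups).to_csv(p, index=False)
        written["descriptive_statistics"] = p
    if linear_rows:
        p = out_dir / "linear_models.csv"
        linear_summary_table(linear_rows).to_csv(p, index=False)
        written["linear_models"] = p
    if rf_results:
        p = out_dir / "rf_models.csv"
        rf_summary_table(rf_results).to_csv(p, index=False)
        written["rf_models"] = p
        metrics_json = {
            res.strategy: {
                "hyperparameters": res.hyperparameters,
                "r2_cal": res.metrics.r2_cal,
                "rmse_cal": res.metrics.rmse_cal,
                "r2_val": res.metrics.r2_val,
                "rmse_val": res.metrics.rmse_val,
                "rpiq": res.metrics.rpiq,
                "category": res.metrics.category,
                "importance_percent": res.importance,
            }
            for res in rf_results
        }
        p = out_dir / "rf_metrics.json"
        p.write_text(json.dumps(metrics_json, indent=2, sort_keys=True))
        written["rf_metrics"] = p
        for res in rf_results:
            p = out_dir / f"importance_{res.strategy.replace('+', '_')}.csv"
            importance_table(res).to_csv(p, index=False)
            written[f"importance_{res.strategy}"] = p
        if figures and y_cal is not None and y_val is not None:
            for res in rf_results:
                fig = scatter_figure(y_cal, res.pred_cal, y_val, res.pred_val, title=res.strategy)
                p = out_dir / f"scatter_{res.strategy.replace('+', '_')}.png"
                fig.savefig(p, dpi=110)
                plt.close(fig)
                written[f"scatter_{res.strategy}"] = p
            fig, ax = plt.subplots(figsize=(7, 4))
            last = rf_results[-1]
            ax.bar(list(last.importance), list(last.importance.values()), color="tab:blue")
            ax.set_ylabel("importance (%)")
            ax.set_title(f"Normalized variable importance: {last.strategy}")
            ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            p = out_dir / "importance_bars.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written["importance_bars"] = p
    if selections:
        p = out_dir / "selected_indices.json"
        payload = {
            name: {"bands_nm": list(sel.bands), "r_cal": sel.r_cal, "r_val": sel.r_val,
                   "err": sel.err}
            for name, sel in selections.items()
        }
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written["selected_indices"] = p
    if figures and two_band_maps:
        for name, cmap in two_band_maps.items():
            fig = contour_figure(cmap, title=name)
            p = out_dir / f"map_{name}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written[f"map_{name}"] = p
    return written
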