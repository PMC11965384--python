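"""Transect-level analysis: per-plot fits, selection tallies, richness/cover
summaries and smoothed parameter trends along the elevational gradient.

The smoother is a locally weighted linear regression (loess-style): tri-cube
kernel over a span fraction of the plots, with observation weights
proportional to the inverse standard error of each plot's parameter estimate,
evaluated with a pointwise standard error on a uniform elevation grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import FitOptions
from .scales import CoverScale, bin_cover_values, get_scale
from .selection import ModelComparison, compare_models

__all__ = [
    "TransectResults",
    "TrendCurve",
    "fit_transect",
    "selection_tally",
    "richness_cover_summary",
    "parameter_trend",
    "validate_plot_table",
]

log = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("plot_id", "elevation_m", "species_id", "cover")


def validate_plot_table(plots: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical long plot table: required columns, positive
    elevations, unique (plot, species) pairs, covers in (0, 1]."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table missing column(s): {missing}")
    if len(plots) == 0:
        raise ValueError("plot table is empty")
    if (plots["elevation_m"] <= 0).any():
        raise ValueError("elevations must be positive")
    dup = plots.duplicated(subset=["plot_id", "species_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"duplicate (plot_id, species_id) pair at row {i}")
    cov = plots["cover"].to_numpy(dtype=float)
    if np.any((cov <= 0) | (cov > 1)):
        raise ValueError("covers must lie in (0, 1] (proportion scale)")
    return plots


@dataclass
class TransectResults:
    """Per-plot model comparisons plus plot metadata for a whole transect."""

    comparisons: dict[str, ModelComparison]
    meta: pd.DataFrame  # per plot: elevation_m, richness
    scale: CoverScale
    failures: dict[str, str] = field(default_factory=dict)


def fit_transect(
    plots: pd.DataFrame,
    models: list | None = None,
    scale: CoverScale | str = "londo",
    options: FitOptions | None = None,
    **compare_kwargs,
) -> TransectResults:
    """Bin and compare all candidate models on every plot of a transect.

    A plot whose comparison fails is recorded in ``failures`` and skipped;
    the transect run never aborts on one bad plot.
    """
    validate_plot_table(plots)
    if isinstance(scale, str):
        scale = get_scale(scale)
    comparisons: dict[str, ModelComparison] = {}
    failures: dict[str, str] = {}
    meta_rows = []
    for plot_id, grp in plots.groupby("plot_id", sort=False):
        elev = float(grp["elevation_m"].iloc[0])
        counts = bin_cover_values(grp["cover"].to_numpy(dtype=float), scale)
        meta_rows.append(
            {"plot_id": plot_id, "elevation_m": elev, "richness": counts.richness}
        )
        try:
            comparisons[plot_id] = compare_models(
                counts, models, options, **compare_kwargs
            )
        except Exception as err:  # recorded, never fatal for the transect
            log.warning("plot %s: comparison failed: %s", plot_id, err)
            failures[str(plot_id)] = str(err)
    meta = pd.DataFrame(meta_rows).set_index("plot_id")
    return TransectResults(comparisons, meta, scale, failures)


def selection_tally(results: TransectResults) -> pd.DataFrame:
    """Count, per elevation belt and model, the plots where the model is in
    the equally-plausible set; append grand totals and the fraction of plots
    in which each model is plausible."""
    if not results.comparisons:
        raise ValueError("no fitted plots to tally")
    model_names = sorted(
        {m for cmp in results.comparisons.values() for m in cmp.plausible}
    )
    rows = {}
    for plot_id, cmp in results.comparisons.items():
        elev = float(results.meta.loc[plot_id, "elevation_m"])
        row = rows.setdefault(elev, dict.fromkeys(model_names, 0))
        for m in cmp.plausible_set():
            row[m] += 1
    tally = (
        pd.DataFrame.from_dict(rows, orient="index")
        .sort_index()
        .rename_axis("elevation_m")
    )
    n_plots = len(results.comparisons)
    tally.loc["total"] = tally.sum()
    tally.loc["fraction"] = tally.loc["total"] / n_plots
    return tally


def richness_cover_summary(plots: pd.DataFrame) -> pd.DataFrame:
    """Per-belt mean/min/max of per-plot species richness and, when recorded,
    of per-plot total cover (percent)."""
    validate_plot_table(plots)
    per_plot = (
        plots.groupby(["elevation_m", "plot_id"])
        .agg(richness=("species_id", "size"))
        .reset_index()
    )
    if "total_cover_percent" in plots.columns:
        cover = (
            plots.groupby(["elevation_m", "plot_id"])["total_cover_percent"]
            .first()
            .reset_index()
        )
        per_plot = per_plot.merge(cover, on=["elevation_m", "plot_id"])
    agg = {"richness": ["mean", "min", "max"]}
    if "total_cover_percent" in per_plot.columns:
        agg["total_cover_percent"] = ["mean", "min", "max"]
    out = per_plot.groupby("elevation_m").agg(agg)
    out.columns = ["_".join(c) for c in out.columns]
    return out


@dataclass
class TrendCurve:
    """A smoothed parameter-versus-elevation curve with pointwise SEs."""

    grid: np.ndarray
    value: np.ndarray
    se: np.ndarray
    weights: np.ndarray  # observation weights actually used (inverse SEs)
    n_used: int
    excluded: list[str] = field(default_factory=list)


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0, 1)
    return (1 - u**3) ** 3


def _local_linear(x, y, w_obs, x0, span):
    """Weighted local linear fit at x0; returns (value, se)."""
    n = x.size
    d = np.abs(x - x0)
    q = max(2, int(np.ceil(span * n)))
    h = np.sort(d)[min(q, n) - 1]
    if h <= 0:
        h = max(d.max(), 1e-12)
    w = _tricube(d / h) * w_obs
    use = w > 0
    if use.sum() < 2:
        return np.nan, np.nan
    xc = x[use] - x0
    yv = y[use]
    wv = w[use]
    X = np.column_stack([np.ones(xc.size), xc])
    XtW = X.T * wv
    A = XtW @ X
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    beta = Ainv @ (XtW @ yv)
    resid = yv - X @ beta
    # local residual variance with an effective-sample-size df correction;
    # both it and the sandwich below are invariant to rescaling the weights
    n_eff = wv.sum() ** 2 / (wv**2).sum()
    sigma2 = float(np.dot(wv, resid**2) / wv.sum()) * n_eff / max(n_eff - 2.0, 1.0)
    B = (X.T * wv**2) @ X
    var0 = sigma2 * (Ainv @ B @ Ainv)[0, 0]
    return float(beta[0]), float(np.sqrt(max(var0, 0.0)))


def parameter_trend(
    results: TransectResults,
    model: str,
    parameter: str,
    span: float = 0.75,
    grid_size: int = 100,
) -> TrendCurve:
    """Loess-style trend of one fitted parameter against elevation.

    Uses every plot with a converged fit of ``model`` and a finite standard
    error for ``parameter``; observation weights are proportional to 1/SE
    (so an estimate with huge uncertainty contributes ~nothing).  Plots
    lacking SEs are excluded and reported.  Requires at least 5 usable plots.
    """
    xs, ys, ses, excluded = [], [], [], []
    for plot_id, cmp in results.comparisons.items():
        fit = cmp.fits.get(model)
        if fit is None or not fit.converged:
            excluded.append(str(plot_id))
            continue
        try:
            idx = fit.model.param_names.index(parameter)
        except ValueError:
            raise KeyError(
                f"model {model!r} has no parameter {parameter!r}; "
                f"available: {fit.model.param_names}"
            ) from None
        se = float(np.atleast_1d(fit.se)[idx])
        if not np.isfinite(se) or se <= 0:
            excluded.append(str(plot_id))
            continue
        xs.append(float(results.meta.loc[plot_id, "elevation_m"]))
        ys.append(float(np.atleast_1d(fit.theta_hat)[idx]))
        ses.append(se)
    if excluded:
        log.warning(
            "parameter_trend(%s.%s): %d plot(s) without usable SEs excluded",
            model, parameter, len(excluded),
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    w_raw = 1.0 / np.asarray(ses)
    # an estimate with negligible relative weight would still widen the
    # span-based bandwidth; treat it as absent altogether
    keep = w_raw / w_raw.max() > 1e-6 if len(xs) else np.zeros(0, bool)
    x, y, w_raw = x[keep], y[keep], w_raw[keep]
    n = x.size
    if n < 5:
        raise ValueError(
            f"parameter_trend needs >= 5 plots with converged fits and SEs; got {n}"
        )
    w_obs = w_raw
    w_obs = w_obs / w_obs.mean()  # invariant to uniform SE rescaling
    grid = np.linspace(x.min(), x.max(), grid_size)
    value = np.empty(grid_size)
    se_out = np.empty(grid_size)
    for i, x0 in enumerate(grid):
        value[i], se_out[i] = _local_linear(x, y, w_obs, x0, span)
    return TrendCurve(grid, value, se_out, w_obs, n, excluded)
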