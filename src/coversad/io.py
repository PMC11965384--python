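"""Reading plot tables and writing fit reports.

The canonical input is a long table (plot_id, elevation_m, species_id,
cover); wide species-by-plot matrices are accepted and melted.  Cover may be
recorded as a percent, a proportion, a 1-based class index, or a symbolic
class label resolved through a label map — class-coded covers are replaced by
their class midpoints, the standard best estimate for interval-censored
cover.  All covers are held internally as proportions in (0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gradient import TransectResults, validate_plot_table
from .scales import CoverScale, class_midpoints, get_scale

__all__ = ["FitReport", "read_plot_table", "write_fit_report", "build_fit_report"]

_COVER_KINDS = ("percent", "proportion", "class_index", "label")


def _resolve_covers(
    raw: pd.Series,
    cover_kind: str,
    scale: CoverScale,
    label_map: Mapping[str, int] | None,
) -> np.ndarray:
    if cover_kind == "proportion":
        return raw.to_numpy(dtype=float)
    if cover_kind == "percent":
        return raw.to_numpy(dtype=float) / 100.0
    mids = class_midpoints(scale)
    if cover_kind == "class_index":
        idx = raw.to_numpy()
        bad = [
            (i, v) for i, v in enumerate(idx)
            if not (float(v).is_integer() and 1 <= int(v) <= scale.n_classes)
        ]
        if bad:
            i, v = bad[0]
            raise ValueError(
                f"row {i}: class index {v!r} outside 1..{scale.n_classes}"
            )
        return mids[idx.astype(int) - 1]
    if cover_kind == "label":
        if label_map is None:
            if scale.labels is not None:
                label_map = {lab: i + 1 for i, lab in enumerate(scale.labels)}
            else:
                raise ValueError("cover_kind='label' requires a label map")
        out = np.empty(len(raw))
        for i, lab in enumerate(raw):
            if lab not in label_map:
                raise ValueError(f"row {i}: unmapped cover label {lab!r}")
            out[i] = mids[int(label_map[lab]) - 1]
        return out
    raise ValueError(f"cover_kind must be one of {_COVER_KINDS}, got {cover_kind!r}")


def read_plot_table(
    path: str | Path,
    cover_kind: str = "percent",
    scale: CoverScale | str = "londo",
    label_map: Mapping[str, int] | None = None,
    columns: Mapping[str, str] | None = None,
    wide: bool = False,
    sep: str = ",",
) -> pd.DataFrame:
    """Read and validate a plot table, returning covers as proportions.

    ``columns`` renames input columns onto the canonical names.  With
    ``wide=True`` the file is a species-by-plot matrix whose first two rows
    are plot ids and elevations (columns = plots); it is melted to long form,
    zeros dropped as absences.
    """
    if isinstance(scale, str):
        scale = get_scale(scale)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if wide:
        raw = pd.read_csv(path, sep=sep, index_col=0)
        elevations = raw.iloc[0]
        mat = raw.iloc[1:]
        long = mat.reset_index().melt(
            id_vars=mat.index.name or "index",
            var_name="plot_id",
            value_name="_raw_cover",
        )
        long.columns = ["species_id", "plot_id", "_raw_cover"]
        long["elevation_m"] = long["plot_id"].map(elevations).astype(float)
        long = long[pd.to_numeric(long["_raw_cover"], errors="coerce").fillna(0) != 0]
        df = long.reset_index(drop=True)
    else:
        df = pd.read_csv(path, sep=sep)
        if columns:
            df = df.rename(columns=dict(columns))
        df = df.rename(columns={"cover": "_raw_cover"})
    for col in ("plot_id", "elevation_m", "species_id", "_raw_cover"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col.lstrip('_').replace('_raw_', '')!r}")
    df["cover"] = _resolve_covers(df["_raw_cover"], cover_kind, scale, label_map)
    df = df.drop(columns=["_raw_cover"])
    cov = df["cover"].to_numpy(dtype=float)
    bad = np.flatnonzero((cov <= 0) | (cov > 1) | ~np.isfinite(cov))
    if bad.size:
        raise ValueError(
            f"{path}: cover out of range (0, 1] at row {bad[0]}: {cov[bad[0]]}"
        )
    df["elevation_m"] = df["elevation_m"].astype(float)
    return validate_plot_table(df.reset_index(drop=True))


@dataclass
class FitReport:
    """Flat per-plot-per-model records plus run metadata."""

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)


_REPORT_COLUMNS = [
    "plot_id", "elevation_m", "model", "params", "se", "loglik", "k", "n",
    "aicc", "delta_aicc", "plausible", "chisq", "gof_df", "gof_p", "converged",
]


def build_fit_report(results: TransectResults, metadata: dict | None = None) -> FitReport:
    """Flatten transect results into one record per (plot, model)."""
    rows = []
    for plot_id, cmp in results.comparisons.items():
        elev = float(results.meta.loc[plot_id, "elevation_m"])
        for m, fit in cmp.fits.items():
            gof = cmp.gof.get(m)
            rows.append(
                {
                    "plot_id": plot_id,
                    "elevation_m": elev,
                    "model": m,
                    "params": json.dumps(
                        {k: float(v) for k, v in fit.params.items()}
                    ),
                    "se": json.dumps([float(s) for s in np.atleast_1d(fit.se)]),
                    "loglik": float(fit.loglik),
                    "k": fit.k,
                    "n": fit.n,
                    "aicc": float(fit.aicc),
                    "delta_aicc": float(cmp.delta_aicc[m]),
                    "plausible": bool(cmp.plausible[m]),
                    "chisq": float(gof.statistic) if gof and gof.available else np.nan,
                    "gof_df": int(gof.df) if gof and gof.available else 0,
                    "gof_p": float(gof.p_value) if gof and gof.available else np.nan,
                    "converged": bool(fit.converged),
                }
            )
    records = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    meta = {"scale": results.scale.name, "n_plots": len(results.comparisons)}
    if metadata:
        meta.update(metadata)
    return FitReport(records, meta)


def write_fit_report(report: FitReport, path: str | Path, fmt: str = "csv") -> Path:
    """Write a fit report as CSV (default; metadata as '# key: value' header
    comments) or JSON (records + metadata object)."""
    path = Path(path)
    if fmt == "csv":
        with open(path, "w") as fh:
            for key, val in report.metadata.items():
                fh.write(f"# {key}: {val}\n")
            report.records.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {
            "metadata": report.metadata,
            "records": json.loads(report.records.to_json(orient="records")),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    return path


def read_fit_report(path: str | Path) -> FitReport:
    """Read back a report written by :func:`write_fit_report`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        records = pd.DataFrame(payload["records"], columns=_REPORT_COLUMNS)
        return FitReport(records, payload["metadata"])
    metadata = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            metadata[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        records = pd.read_csv(fh)
    return FitReport(records, metadata)
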