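"""Marker-gene time courses, TF-family heatmap matrices and photoperiod.

Time-course summaries report per-time-point mean/min/max across replicates
(the mean dot plus a bar spanning lowest and highest replicate).  Heatmap
matrices carry RPKM values of family members passing a CPM-sum detectability
filter.  Day length comes from a closed-form solar model (declination from
day of year, hour angle at -0.833 deg solar altitude) accurate to a few
minutes at temperate latitudes.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyHeatmapError,
    MissingGeneError,
    UnsupportedLatitudeError,
)
from .io_formats import EnvSeries, GeneSet, SampleSheet
from .normalization import ExpressionMatrix, filter_by_expression_sum

__all__ = [
    "TimeCourseSummary",
    "HeatmapMatrix",
    "DayLengthSeries",
    "replicate_summary",
    "family_heatmap",
    "day_length",
    "day_length_series",
    "plot_time_course",
    "plot_heatmap",
]

SCALINGS = ("none", "row_max", "row_z")
MAX_SUPPORTED_LATITUDE = 66.0


@dataclass(frozen=True)
class TimeCourseSummary:
    """Per-time-point mean/min/max of one gene's expression across replicates."""

    gene_id: str
    unit: str
    records: pd.DataFrame  # columns: timepoint, date, mean, min, max; date order

    def __post_init__(self) -> None:
        df = self.records
        if not (
            (df["min"] <= df["mean"] + 1e-12) & (df["mean"] <= df["max"] + 1e-12)
        ).all():
            raise ValueError("min <= mean <= max violated")
        if not df["date"].is_monotonic_increasing:
            raise ValueError("records must be in date order")


@dataclass(frozen=True)
class HeatmapMatrix:
    """Gene-by-date matrix for family heatmaps, optionally row-scaled."""

    values: pd.DataFrame  # rows: display names, columns: dates
    scaling: str

    def __post_init__(self) -> None:
        if self.scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}")
        if self.values.shape[0] < 1:
            raise EmptyHeatmapError("heatmap has no rows")
        if self.scaling == "row_max":
            row_max = self.values.max(axis=1)
            if not np.allclose(row_max.to_numpy(), 1.0):
                raise ValueError("row_max scaling requires each row max == 1")


@dataclass(frozen=True)
class DayLengthSeries:
    """Day length in hours per date at a fixed latitude."""

    latitude_deg: float
    series: pd.Series  # index: date, values: hours

    def __post_init__(self) -> None:
        vals = self.series.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 24):
            raise ValueError("day length outside [0, 24] hours")


def replicate_summary(
    expr: ExpressionMatrix, sheet: SampleSheet, gene_id: str
) -> TimeCourseSummary:
    """Mean/min/max across replicates per time point for one gene."""
    if gene_id not in expr.data.index:
        raise MissingGeneError(f"gene {gene_id!r} not in expression matrix")
    values = expr.data.loc[gene_id]
    rows = []
    for tp, grp in sheet.records.groupby("timepoint", sort=False):
        reps = values[grp["sample_id"]].to_numpy(dtype=float)
        rows.append(
            {
                "timepoint": tp,
                "date": grp["date"].iloc[0],
                "mean": float(reps.mean()),
                "min": float(reps.min()),
                "max": float(reps.max()),
            }
        )
    rows.sort(key=lambda r: r["date"])
    return TimeCourseSummary(gene_id, expr.unit, pd.DataFrame(rows))


def family_heatmap(
    expr: ExpressionMatrix,
    family: GeneSet | Sequence[str],
    cpm_expr: ExpressionMatrix,
    threshold: float = 10.0,
    scaling: str = "none",
    sheet: SampleSheet | None = None,
    display_names: Mapping[str, str] | None = None,
) -> HeatmapMatrix:
    """RPKM heatmap matrix of a gene family, detectability-filtered on CPM.

    Family members whose CPM sum falls below ``threshold`` are dropped; rows
    keep the input family order, columns are per-sample in date order (or
    sample order when no sheet is given).
    """
    members = (
        family.sorted_members() if isinstance(family, GeneSet) else list(family)
    )
    if not members:
        raise EmptyHeatmapError("empty gene family")
    missing = [g for g in members if g not in expr.data.index]
    if missing:
        raise MissingGeneError(f"family genes absent from matrix: {missing}")
    passing = filter_by_expression_sum(cpm_expr, threshold)
    kept = [g for g in members if g in passing]
    if scaling == "row_max":
        kept = [g for g in kept if expr.data.loc[g].max() > 0]
    if not kept:
        raise EmptyHeatmapError(
            f"all {len(members)} family members fall below CPM sum {threshold}"
        )
    sub = expr.data.loc[kept].copy()
    if sheet is not None:
        order = sheet.records.sort_values(["date", "sample_id"], kind="mergesort")
        sub = sub.loc[:, order["sample_id"].tolist()]
        sub.columns = [
            f"{d.isoformat()}|{s}"
            for d, s in zip(order["date"], order["sample_id"])
        ]
    if display_names:
        sub.index = [display_names.get(g, g) for g in sub.index]
    if scaling == "row_max":
        sub = sub.div(sub.max(axis=1), axis=0)
    elif scaling == "row_z":
        sub = sub.sub(sub.mean(axis=1), axis=0).div(
            sub.std(axis=1, ddof=1).replace(0, np.nan), axis=0
        ).fillna(0.0)
    return HeatmapMatrix(sub, scaling)


def _solar_declination(day_of_year: int) -> float:
    """Solar declination in radians (Fourier-series approximation)."""
    g = 2.0 * math.pi / 365.0 * (day_of_year - 1 + 0.5)
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def day_length(date: _dt.date, latitude_deg: float) -> float:
    """Hours between sunrise and sunset at the given latitude and date.

    Sunrise/sunset are taken at a solar altitude of -0.833 deg (atmospheric
    refraction plus the solar radius).  Polar latitudes are rejected.
    """
    if abs(latitude_deg) > MAX_SUPPORTED_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude_deg} outside supported +/-{MAX_SUPPORTED_LATITUDE}"
        )
    lat = math.radians(latitude_deg)
    decl = _solar_declination(date.timetuple().tm_yday)
    alt = math.radians(-0.833)
    cos_h = (math.sin(alt) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    cos_h = max(-1.0, min(1.0, cos_h))
    return 2.0 * math.degrees(math.acos(cos_h)) / 15.0


def day_length_series(
    dates: Sequence[_dt.date], latitude_deg: float
) -> DayLengthSeries:
    values = pd.Series(
        [day_length(d, latitude_deg) for d in dates],
        index=pd.Index(list(dates), name="date"),
    )
    return DayLengthSeries(latitude_deg, values)


# ---------------------------------------------------------------------------
# plotting (thin matplotlib wrappers; aesthetics are not a goal)
# ---------------------------------------------------------------------------


def plot_time_course(
    summary: TimeCourseSummary,
    path: str,
    env: EnvSeries | None = None,
    daylength: DayLengthSeries | None = None,
) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    df = summary.records
    dates = pd.to_datetime(df["date"])
    ax.vlines(dates, df["min"], df["max"], color="0.6", lw=3)
    ax.plot(dates, df["mean"], "o-", color="tab:blue", label=summary.gene_id)
    ax.set_ylabel(summary.unit)
    if env is not None:
        ax2 = ax.twinx()
        ax2.plot(
            pd.to_datetime(env.dates),
            env.series.to_numpy(),
            "--",
            color="tab:orange",
            alpha=0.7,
        )
        ax2.set_ylabel("temperature (deg C)")
    if daylength is not None:
        ax3 = ax.twinx()
        ax3.spines.right.set_position(("outward", 50))
        ax3.plot(
            pd.to_datetime(daylength.series.index),
            daylength.series.to_numpy(),
            ":",
            color="tab:green",
            alpha=0.7,
        )
        ax3.set_ylabel("day length (h)")
    ax.legend(loc="upper left")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(matrix: HeatmapMatrix, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(6, matrix.values.shape[1] * 0.3), max(3, matrix.values.shape[0] * 0.3))
    )
    im = ax.imshow(matrix.values.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(matrix.values.shape[0]))
    ax.set_yticklabels(matrix.values.index, fontsize=7)
    ax.set_xticks(range(matrix.values.shape[1]))
    ax.set_xticklabels(matrix.values.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"scaling={matrix.scaling}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
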