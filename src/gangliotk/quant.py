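"""Internal-standard calibration, LOD/LOQ, percent recovery, and
relative-abundance profiles.

Calibration regresses the response ratio (analyte peak area / internal
standard peak area) on concentration by ordinary least squares; an
optional 1/x weighting is available for heteroscedastic series.  Detection
and quantitation limits follow the ICH convention

    LOD = 3.3 * s_y / slope,    LOQ = 10 * s_y / slope,

with s_y the residual standard error of the fit.  Relative abundance is a
species' integrated area as a percentage of the summed area per replicate,
reported as mean +/- sd across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "RecoveryResult",
    "ProfileSummary",
    "fit_calibration",
    "percent_recovery",
    "recovery_summary",
    "relative_abundance",
]


@dataclass(frozen=True)
class CalibrationModel:
    """An internal-standard calibration line y = slope*c + intercept."""

    slope: float
    intercept: float
    r_squared: float
    residual_se: float
    lod: float  # ng/uL
    loq: float  # ng/uL
    points: tuple[tuple[float, float], ...]

    def predict_response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def quantify(self, response_ratio: float) -> float:
        """Invert the line: concentration from an observed response ratio."""
        return (response_ratio - self.intercept) / self.slope


def fit_calibration(
    points: list[tuple[float, float]] | np.ndarray,
    weighting: str = "none",
) -> CalibrationModel:
    """Fit a calibration line to (concentration, response ratio) points.

    ``weighting``: ``"none"`` (default, ordinary least squares) or
    ``"1/x"`` (weights inversely proportional to concentration).
    R^2 is computed on the unweighted residuals in both cases.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, response) points")
    c, y = pts[:, 0], pts[:, 1]
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if weighting == "none":
        w = np.ones_like(c)
    elif weighting == "1/x":
        if np.any(c <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / c
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    W = np.sqrt(w)
    X = np.column_stack([c * W, W])
    coef, *_ = np.linalg.lstsq(X, y * W, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * c + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    s_y = float(np.sqrt(ss_res / (len(y) - 2)))
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        residual_se=s_y,
        lod=3.3 * s_y / slope,
        loq=10.0 * s_y / slope,
        points=tuple(map(tuple, pts)),
    )


def percent_recovery(measured: float, spiked: float) -> float:
    """Percent of a spiked internal-standard amount that was measured back:
    100 * measured / spiked."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    if measured < 0:
        raise ValueError("measured amount must be non-negative")
    return 100.0 * measured / spiked


@dataclass(frozen=True)
class RecoveryResult:
    """Replicate percent recoveries with their mean and sd (ddof=1)."""

    replicate_percentages: tuple[float, ...]
    mean: float
    sd: float


def recovery_summary(
    measured: list[float] | None = None,
    spiked: list[float] | float | None = None,
    *,
    percentages: list[float] | None = None,
) -> RecoveryResult:
    """Summarize replicate recoveries, either from measured/spiked amount
    pairs or from already-computed percentages."""
    if percentages is None:
        if measured is None or spiked is None:
            raise ValueError("provide measured+spiked or percentages")
        spiked_list = (
            [float(spiked)] * len(measured)
            if np.isscalar(spiked)
            else list(spiked)  # type: ignore[arg-type]
        )
        percentages = [percent_recovery(m, s)
                       for m, s in zip(measured, spiked_list, strict=True)]
    arr = np.asarray(percentages, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RecoveryResult(tuple(map(float, arr)), float(arr.mean()), sd)


@dataclass(frozen=True)
class ProfileSummary:
    """Percent relative abundance per species, mean +/- sd over replicates,
    ranked by mean descending; plus the total area per replicate."""

    table: pd.DataFrame  # columns: species, pct_mean, pct_sd
    per_replicate: pd.DataFrame  # columns: replicate, species, pct, area
    totals: pd.DataFrame  # columns: replicate, total_area


def relative_abundance(areas: pd.DataFrame) -> ProfileSummary:
    """Percent relative abundance from a long-format area table.

    ``areas`` needs columns ``species``, ``replicate``, ``area`` (areas
    >= 0).  Within each replicate, species percentage = 100 * area / total
    area; percentages therefore sum to 100 per replicate.  Species absent
    from a replicate contribute zero area to it.
    """
    required = {"species", "replicate", "area"}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"areas table missing columns: {sorted(missing)}")
    if (areas["area"] < 0).any():
        raise ValueError("areas must be non-negative")
    wide = (
        areas.pivot_table(index="replicate", columns="species", values="area",
                          aggfunc="sum", fill_value=0.0)
    )
    totals = wide.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"replicate(s) with zero total area: {list(zero.index)}"
        )
    pct = wide.div(totals, axis=0) * 100.0
    long = (
        pct.reset_index()
        .melt(id_vars="replicate", var_name="species", value_name="pct")
        .merge(
            wide.reset_index().melt(
                id_vars="replicate", var_name="species", value_name="area"
            ),
            on=["replicate", "species"],
        )
    )
    summary = (
        pct.agg(["mean", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0])
        .T.reset_index()
    )
    summary.columns = ["species", "pct_mean", "pct_sd"]
    summary = summary.sort_values(
        "pct_mean", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    totals_df = totals.reset_index()
    totals_df.columns = ["replicate", "total_area"]
    return ProfileSummary(table=summary, per_replicate=long, totals=totals_df)
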