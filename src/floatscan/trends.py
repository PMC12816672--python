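"""Monotone-trend statistics for monthly area series.

Workflow: subtract the calendar-month climatology (de-seasoning), test for a
monotone trend with the two-sided Mann-Kendall test (tie-corrected variance),
and estimate the trend magnitude with the Theil-Sen median slope and its
rank-based 95% confidence interval.  Rates are reported in percent per year
against an explicit baseline convention.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .compositing import AreaSeries

__all__ = [
    "TrendResult",
    "deseason",
    "mann_kendall",
    "theil_sen",
    "percent_per_year",
    "analyze_series",
]


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall + Theil-Sen summary for one de-seasoned series."""

    s_statistic: float
    var_s: float
    z: float
    p_value: float
    slope: float  # area per month
    slope_ci: tuple[float, float]  # 95% unless stated otherwise
    percent_per_year: float
    n: int
    baseline: float = np.nan
    baseline_convention: str = "first_year_mean"

    def to_dict(self) -> dict:
        return asdict(self)


def deseason(values: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Anomalies after removing the calendar-month climatology.

    ``anomaly(t) = value(t) - mean(values in the same calendar month)``; the
    per-month mean of the anomalies is zero by construction.
    """
    values = np.asarray(values, dtype=float)
    months = np.asarray(months, dtype=int)
    if values.size != months.size:
        raise ValueError("values/months length mismatch")
    if values.size < 24:
        raise ValueError("need at least 24 months to estimate a seasonal cycle")
    anom = values.copy()
    for m in np.unique(months):
        sel = months == m
        anom[sel] -= values[sel].mean()
    return anom


def mann_kendall(x: np.ndarray) -> tuple[float, float, float, float]:
    """Two-sided Mann-Kendall test: returns (S, Var(S), Z, p).

    S counts concordant minus discordant pairs; Var(S) carries the standard
    tie correction; Z applies the +/-1 continuity correction; p is the
    two-sided normal tail probability.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 points")
    diff = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(var_s), float(z), float(p)


def theil_sen(
    x: np.ndarray, t: np.ndarray | None = None, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Theil-Sen slope with a rank-based confidence interval.

    Slope is the median of all pairwise slopes ``(x_j - x_i)/(t_j - t_i)``
    over i < j (``t`` defaults to 0..n-1; true month gaps should be passed
    when the series has holes).  The CI picks order statistics of the sorted
    pairwise slopes at ranks ``(N -/+ z * sqrt(VarS)) / 2``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 points")
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, dtype=float)
    if t.size != n:
        raise ValueError("t/x length mismatch")
    i, j = np.triu_indices(n, k=1)
    dt = t[j] - t[i]
    ok = dt != 0
    slopes = np.sort((x[j] - x[i])[ok] / dt[ok])
    slope = float(np.median(slopes))
    _, var_s, _, _ = mann_kendall(x)
    c = stats.norm.ppf(1 - alpha / 2) * np.sqrt(var_s)
    n_slopes = slopes.size
    m1 = int(np.round((n_slopes - c) / 2))
    m2 = int(np.round((n_slopes + c) / 2))
    lo = float(slopes[max(0, min(m1, n_slopes - 1))])
    hi = float(slopes[max(0, min(m2, n_slopes - 1))])
    return slope, min(lo, slope), max(hi, slope)


def percent_per_year(
    slope_per_month: float,
    series: AreaSeries,
    fa_type=None,
    zone=None,
    baseline: str = "first_year_mean",
) -> tuple[float, float]:
    """Annualised relative rate: ``100 * 12 * slope / baseline_area``.

    ``baseline='first_year_mean'`` (default) uses the mean area of the first
    calendar year present; ``'series_mean'`` uses the whole-series mean.
    Returns (percent_per_year, baseline_area).
    """
    _, years, areas = series.values(fa_type, zone)
    if baseline == "first_year_mean":
        base = float(areas[years == years.min()].mean())
    elif baseline == "series_mean":
        base = float(areas.mean())
    else:
        raise ValueError(f"unknown baseline convention {baseline!r}")
    if base <= 0:
        raise ValueError("baseline area must be positive")
    return 100.0 * 12.0 * slope_per_month / base, base


def analyze_series(
    series: AreaSeries,
    fa_type=None,
    zone=None,
    alpha: float = 0.05,
    baseline: str = "first_year_mean",
) -> TrendResult:
    """De-season one selection of a series and run the full trend analysis."""
    t, _, areas = series.values(fa_type, zone)
    df = series.select(fa_type, zone)
    months = (
        pd.DataFrame({"t": series.calendar_index(df), "m": df["month"]})
        .groupby("t")["m"].first().to_numpy()
        if len(df)
        else np.array([], dtype=int)
    )
    anom = deseason(areas, months)
    s, var_s, z, p = mann_kendall(anom)
    slope, lo, hi = theil_sen(anom, t=t.astype(float), alpha=alpha)
    pct, base = percent_per_year(slope, series, fa_type, zone, baseline=baseline)
    return TrendResult(
        s_statistic=s,
        var_s=var_s,
        z=z,
        p_value=p,
        slope=slope,
        slope_ci=(lo, hi),
        percent_per_year=pct,
        n=int(areas.size),
        baseline=base,
        baseline_convention=baseline,
    )


def trend_table(series: AreaSeries, alpha: float = 0.05, baseline: str = "first_year_mean") -> pd.DataFrame:
    """One TrendResult row per (fa_type, zone) present in the series."""
    rows = []
    for (fa_type, zone), _ in series.frame.groupby(["fa_type", "zone"]):
        res = analyze_series(series, fa_type, zone, alpha=alpha, baseline=baseline)
        rows.append(
            {"fa_type": fa_type, "zone": zone, "S": res.s_statistic, "VarS": res.var_s,
             "Z": res.z, "p": res.p_value, "slope": res.slope, "ci_low": res.slope_ci[0],
             "ci_high": res.slope_ci[1], "pct_per_year": res.percent_per_year, "n": res.n}
        )
    return pd.DataFrame(rows)
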