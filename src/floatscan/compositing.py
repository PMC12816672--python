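"""Temporal compositing of detections into density grids, areas, and footprints.

Per-scene detections are binned into monthly or annual mean-cover grids
(only validly observed cells enter the denominator), integrated into areal
coverage by zone and type, and accumulated into the cumulative footprint —
the union of all cells where algae was ever present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DensityGrid",
    "AreaSeries",
    "ZoneMask",
    "composite",
    "integrate_area",
    "niche_footprint",
    "aggregate_areas",
    "area_series_from_grids",
]


@dataclass
class DensityGrid:
    """Mean sub-pixel cover per cell over one period, with observation counts."""

    grid: np.ndarray
    n_obs: np.ndarray
    period: tuple
    cell_area: float | np.ndarray = 1.0  # scalar km^2, or per-row vector

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if self.grid.shape != self.n_obs.shape:
            raise ValueError("grid/n_obs shape mismatch")
        defined = self.n_obs > 0
        if not np.all(np.isnan(self.grid[~defined])):
            raise ValueError("grid must be NaN where n_obs == 0")
        vals = self.grid[defined]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("mean cover outside [0, 1]")

    def cell_areas(self) -> np.ndarray:
        """Per-cell area array (broadcast of the scalar or per-row vector)."""
        ca = np.asarray(self.cell_area, dtype=float)
        if ca.ndim == 0:
            return np.full(self.grid.shape, float(ca))
        return np.broadcast_to(ca[:, None], self.grid.shape).copy()


@dataclass(frozen=True)
class ZoneMask:
    """A named, non-overlapping analysis zone as a boolean raster."""

    zone_id: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


class AreaSeries:
    """Monthly areal coverage records: (year, month, fa_type, zone, area_km2)."""

    COLUMNS = ("year", "month", "fa_type", "zone", "area_km2")

    def __init__(self, records: pd.DataFrame) -> None:
        df = pd.DataFrame(records).copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (df["area_km2"] < 0).any():
            raise ValueError("areas must be non-negative")
        if df.duplicated(subset=["year", "month", "fa_type", "zone"]).any():
            raise ValueError("one record per (period, type, zone) required")
        df = df.sort_values(["fa_type", "zone", "year", "month"]).reset_index(drop=True)
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def calendar_index(self, df: pd.DataFrame | None = None) -> np.ndarray:
        """Contiguous month index (months since the earliest record)."""
        d = self.frame if df is None else df
        base = int(self.frame["year"].min()) * 12
        return (d["year"].astype(int) * 12 + d["month"].astype(int) - 1 - base).to_numpy()

    def select(self, fa_type=None, zone=None) -> pd.DataFrame:
        df = self.frame
        if fa_type is not None:
            df = df[df["fa_type"] == fa_type]
        if zone is not None:
            df = df[df["zone"] == zone]
        return df.sort_values(["year", "month"]).reset_index(drop=True)

    def values(self, fa_type=None, zone=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time index, year, area) arrays for one type/zone selection.

        Records sharing a calendar month (e.g. several zones) are summed.
        """
        df = self.select(fa_type, zone)
        t = self.calendar_index(df)
        g = pd.DataFrame({"t": t, "year": df["year"], "month": df["month"], "a": df["area_km2"]})
        g = g.groupby(["t", "year", "month"], as_index=False)["a"].sum().sort_values("t")
        return g["t"].to_numpy(), g["year"].to_numpy(), g["a"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AreaSeries":
        return cls(pd.read_csv(path))


def composite(detections, period, cell_area: float | np.ndarray = 1.0, fa_type=None) -> DensityGrid:
    """Mean sub-pixel cover per cell over a list of detections.

    Cells enter the denominator only where the source scene validly observed
    them (``Detection.observed``); clouded / invalid observations are skipped.
    With ``fa_type`` given, only cover attributed to that type contributes to
    the numerator (observations still count).
    """
    detections = list(detections)
    if not detections:
        raise ValueError("empty detection list")
    shape = detections[0].chi.shape
    total = np.zeros(shape, dtype=float)
    n_obs = np.zeros(shape, dtype=int)
    for det in detections:
        if det.chi.shape != shape:
            raise ValueError("detections must share one grid")
        obs = det.observed
        chi = np.where(det.mask, det.chi, 0.0)
        if fa_type is not None:
            code = det.type_legend.index(fa_type)
            chi = np.where(det.fa_type == code, chi, 0.0)
        total[obs] += chi[obs]
        n_obs[obs] += 1
    with np.errstate(invalid="ignore"):
        grid = np.where(n_obs > 0, total / np.maximum(n_obs, 1), np.nan)
    return DensityGrid(grid=grid, n_obs=n_obs, period=tuple(np.atleast_1d(period)), cell_area=cell_area)


def integrate_area(grid: DensityGrid, zone: ZoneMask | None = None) -> float:
    """Algae-covered area: sum of mean cover times cell area over the zone."""
    sel = grid.n_obs > 0
    if zone is not None:
        sel &= zone.mask
    return float(np.sum(grid.grid[sel] * grid.cell_areas()[sel]))


def niche_footprint(grids, threshold: float = 0.0) -> tuple[np.ndarray, float]:
    """Cumulative footprint over periods: union of cells with cover > threshold.

    Returns the boolean footprint mask and its area (cell count x cell area).
    """
    grids = list(grids)
    if not grids:
        raise ValueError("no grids")
    shape = grids[0].grid.shape
    footprint = np.zeros(shape, dtype=bool)
    for g in grids:
        if g.grid.shape != shape:
            raise ValueError("inconsistent grid definitions")
        footprint |= (g.n_obs > 0) & (np.nan_to_num(g.grid) > threshold)
    area = float(np.sum(grids[0].cell_areas()[footprint]))
    return footprint, area


def aggregate_areas(records, fa_types=None, zones=None) -> float:
    """Sum area entries of a (zone, fa_type, area) table with optional filters.

    ``records`` is any DataFrame-convertible with columns ``zone``,
    ``fa_type`` and ``area`` (or ``area_km2``).  This is the bookkeeping
    arithmetic behind per-type / per-zone niche-area summaries.
    """
    df = pd.DataFrame(records)
    col = "area" if "area" in df.columns else "area_km2"
    sel = pd.Series(True, index=df.index)
    if fa_types is not None:
        sel &= df["fa_type"].isin(list(fa_types))
    if zones is not None:
        sel &= df["zone"].isin(list(zones))
    return float(df.loc[sel, col].sum())


def area_series_from_grids(grids_by_period, zones=None, fa_type="all") -> AreaSeries:
    """Build an AreaSeries from {(year, month): DensityGrid} mappings."""
    rows = []
    for (year, month), grid in grids_by_period.items():
        if zones:
            for z in zones:
                rows.append(
                    {"year": year, "month": month, "fa_type": fa_type, "zone": z.zone_id,
                     "area_km2": integrate_area(grid, z)}
                )
        else:
            rows.append(
                {"year": year, "month": month, "fa_type": fa_type, "zone": 0,
                 "area_km2": integrate_area(grid)}
            )
    return AreaSeries(pd.DataFrame(rows))
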