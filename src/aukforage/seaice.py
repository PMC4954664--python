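"""Regional sea-ice concentration summaries and the long-term trend test.

Works on user-supplied daily gridded sea-ice concentration (SIC, %) tables
in long format (date, lon, lat, sic).  The regional summary is the
unweighted mean over grid cells inside a region polygon and days inside a
seasonal window — by default a 150 x 200 km rectangle around the colony over
the chick-rearing weeks.  Cells are weighted equally, which is a good
approximation for a ~12.5 km near-equal-area grid; the cosine-latitude
weighting is available behind a flag.  The interannual trend is an ordinary
least-squares fit of mean SIC on year with t = slope/SE on n - 2 df.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from shapely import contains_xy
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .geo import LocalProjection


def make_region(colony: tuple[float, float], width_km: float = 150.0,
                height_km: float = 200.0) -> Polygon:
    """Rectangle of the given size centred on the colony, as a lon/lat
    polygon (vertices densified along the edges so the projected shape stays
    rectangular)."""
    proj = LocalProjection(*colony)
    hw, hh = width_km / 2.0, height_km / 2.0
    xs = np.linspace(-hw, hw, 21)
    ys = np.linspace(-hh, hh, 21)
    ring = ([(x, -hh) for x in xs] + [(hw, y) for y in ys]
            + [(x, hh) for x in xs[::-1]] + [(-hw, y) for y in ys[::-1]])
    lonlat = [tuple(np.asarray(proj.inverse(x, y), dtype=float)) for x, y in ring]
    return Polygon(lonlat)


def regional_mean(grids: pd.DataFrame, region: BaseGeometry,
                  window: tuple | None = None,
                  area_weighted: bool = False) -> dict:
    """Mean SIC (%) over in-region cells and in-window days.

    ``grids`` has columns date, lon, lat, sic with missing values allowed
    (ignored, count reported).  ``window`` is an inclusive (start, end) pair
    of dates.  Returns mean_sic_pct, n_cells, n_days, n_missing.
    """
    df = grids.copy()
    df["date"] = pd.to_datetime(df["date"])
    if window is not None:
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        df = df[(df.date >= start) & (df.date <= end)]
    if df.empty:
        raise ValueError("no grid dates inside the window")
    inside = contains_xy(region, df.lon.to_numpy(), df.lat.to_numpy())
    df = df[inside]
    if df.empty:
        raise ValueError("region does not intersect the grid")
    missing = df.sic.isna()
    vals = df.sic[~missing].to_numpy(dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("SIC values must lie in [0, 100]")
    if area_weighted:
        w = np.cos(np.radians(df.lat[~missing].to_numpy(dtype=float)))
        mean = float(np.average(vals, weights=w))
    else:
        mean = float(vals.mean())
    return {"mean_sic_pct": mean,
            "n_days": int(df.date.nunique()),
            "n_cells": int(df.groupby("date").size().max()),
            "n_missing": int(missing.sum())}


def regional_series(grids_by_year: dict[int, pd.DataFrame],
                    region: BaseGeometry,
                    window_mmdd: tuple[str, str] = ("07-15", "08-15")) -> pd.Series:
    """Yearly window-mean SIC: applies ``regional_mean`` per year with the
    month-day window anchored in that year."""
    out = {}
    for year, grids in sorted(grids_by_year.items()):
        window = (f"{year}-{window_mmdd[0]}", f"{year}-{window_mmdd[1]}")
        out[year] = regional_mean(grids, region, window)["mean_sic_pct"]
    return pd.Series(out, name="mean_sic_pct")


def trend_test(series: pd.Series) -> dict:
    """OLS trend of yearly mean SIC on year: slope (%/yr), t = slope/SE,
    df = n - 2, two-sided p."""
    years = np.asarray(series.index, dtype=float)
    vals = np.asarray(series.to_numpy(), dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 years for a trend test")
    if np.ptp(vals) == 0:
        raise ValueError("series is constant: slope 0, t undefined")
    res = stats.linregress(years, vals)
    t = float(res.slope / res.stderr) if res.stderr > 0 else np.inf * np.sign(res.slope)
    return {"slope_pct_per_yr": float(res.slope),
            "intercept": float(res.intercept),
            "t": t,
            "df": int(len(years) - 2),
            "p": float(res.pvalue)}
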