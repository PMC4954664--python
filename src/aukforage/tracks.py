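"""GPS track processing: instantaneous speeds, behavioural labels, trip
segmentation and metrics, and distances to the colony / ice edge.

Behaviour is classified from the speed of the great-circle segment ending at
each fix: below 10 km/h the bird is taken to be foraging or resting (the two
cannot be separated at a 15-min fix interval and are merged into one class);
at or above the threshold it is travelling.  The comparison is strict, so a
speed of exactly 10 km/h counts as travel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .geo import LocalProjection, haversine_km

SPEED_THRESHOLD_KMH = 10.0
FORAGE_REST = "forage_rest"
TRAVEL = "travel"


def read_fixes(path) -> pd.DataFrame:
    """Read a fixes CSV (bird_id, timestamp ISO-8601 as ``t``, lon, lat)."""
    df = pd.read_csv(path, parse_dates=["t"])
    required = {"bird_id", "t", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixes CSV missing columns: {sorted(missing)}")
    if (df.lat.abs() > 90).any() or (df.lon.abs() > 180).any():
        raise ValueError("fix coordinates out of WGS84 range")
    return df.sort_values(["bird_id", "t"], kind="stable").reset_index(drop=True)


def compute_speeds(fixes: pd.DataFrame,
                   threshold_kmh: float = SPEED_THRESHOLD_KMH,
                   max_gap_factor: float = 3.0) -> pd.DataFrame:
    """Label each fix with segment speed (km/h) and behaviour.

    The speed at a fix is great-circle distance from the previous fix of the
    same bird divided by the elapsed time.  The first fix of each bird has
    undefined speed and no behaviour.  Segments spanning a time gap longer
    than ``max_gap_factor`` times the bird's median fix interval are flagged
    (``gap=True``) and excluded from behavioural labelling.
    """
    if len(fixes) < 2:
        warnings.warn("fewer than two fixes; no speeds computed")
        out = fixes.copy()
        out["speed_kmh"] = np.nan
        out["behaviour"] = pd.NA
        out["gap"] = False
        return out.iloc[0:0]

    out = fixes.sort_values(["bird_id", "t"], kind="stable").reset_index(drop=True).copy()
    speed = np.full(len(out), np.nan)
    gap = np.zeros(len(out), dtype=bool)
    for bird, idx in out.groupby("bird_id", sort=False).indices.items():
        sub = out.iloc[idx]
        dt_s = sub.t.diff().dt.total_seconds().to_numpy()
        if np.any(dt_s[1:] == 0):
            bad = sub.t.iloc[1:][dt_s[1:] == 0].iloc[0]
            raise ValueError(f"duplicate timestamp for bird {bird} at {bad}")
        if np.any(dt_s[1:] < 0):
            raise ValueError(f"timestamps not increasing for bird {bird}")
        d_km = haversine_km(sub.lon.to_numpy()[:-1], sub.lat.to_numpy()[:-1],
                            sub.lon.to_numpy()[1:], sub.lat.to_numpy()[1:])
        speed[idx[1:]] = d_km / (dt_s[1:] / 3600.0)
        if len(dt_s) > 1:
            med = np.nanmedian(dt_s[1:])
            gap[idx[1:]] = dt_s[1:] > max_gap_factor * med
    out["speed_kmh"] = speed
    labelled = np.isfinite(speed) & ~gap
    behaviour = np.where(speed < threshold_kmh, FORAGE_REST, TRAVEL)
    out["behaviour"] = pd.array(np.where(labelled, behaviour, None))
    out["gap"] = gap
    return out


@dataclass
class Trip:
    """One colony-to-colony excursion of a single bird."""

    bird_id: str
    fixes: pd.DataFrame = field(repr=False)
    complete: bool
    duration_h: float
    path_length_km: float
    max_distance_km: float
    year: int | None = None


def segment_trips(fixes: pd.DataFrame, colony: tuple[float, float],
                  radius_km: float = 1.0) -> list[Trip]:
    """Split a bird's fixes into trips: maximal runs outside the colony
    radius.  A trip is complete when flanked by inside-radius fixes at both
    ends; duration runs from the first to the last outside fix and path
    length sums great-circle segment distances over the outside run.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lon0, lat0 = colony
    trips: list[Trip] = []
    for bird, sub in fixes.groupby("bird_id", sort=False):
        sub = sub.sort_values("t", kind="stable").reset_index(drop=True)
        d_colony = haversine_km(sub.lon.to_numpy(), sub.lat.to_numpy(), lon0, lat0)
        outside = d_colony > radius_km
        if not outside.any():
            continue
        # run boundaries of the `outside` mask
        edges = np.flatnonzero(np.diff(np.concatenate([[0], outside.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):  # [s, e) outside run
            run = sub.iloc[s:e]
            complete = s > 0 and e < len(sub)
            dur = (run.t.iloc[-1] - run.t.iloc[0]).total_seconds() / 3600.0
            lons, lats = run.lon.to_numpy(), run.lat.to_numpy()
            path = float(np.sum(haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:]))) \
                if len(run) > 1 else 0.0
            year = int(run.year.iloc[0]) if "year" in run.columns else None
            trips.append(Trip(bird_id=str(bird), fixes=run, complete=bool(complete),
                              duration_h=float(dur), path_length_km=path,
                              max_distance_km=float(d_colony[s:e].max()),
                              year=year))
    return trips


def rank_sum_test(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns the U statistic of the first sample (the convention R's
    ``wilcox.test`` prints as W) with an exact p-value when the combined
    sample size is at most 20 and there are no ties, otherwise a normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size) <= 20 and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"W": float(res.statistic), "p": float(res.pvalue), "method": method,
            "convention": "U of first sample (R wilcox.test W)"}


def trip_summary(trips: list[Trip], compare: tuple | None = None) -> dict:
    """Per-year mean +- SD of max distance, duration and path length over
    complete trips, with an optional two-group Wilcoxon comparison.

    Incomplete trips contribute to max distance only (duration and path
    length are undefined for a trip that never closed).  ``compare`` names
    two year groups; the test is skipped with a warning for any metric
    where a group has no complete trips.
    """
    rows = []
    for tr in trips:
        rows.append({"bird_id": tr.bird_id, "year": tr.year, "complete": tr.complete,
                     "max_distance_km": tr.max_distance_km,
                     "duration_h": tr.duration_h if tr.complete else np.nan,
                     "path_length_km": tr.path_length_km if tr.complete else np.nan})
    df = pd.DataFrame(rows)
    metrics = ["max_distance_km", "duration_h", "path_length_km"]
    summary = (df.groupby("year")[metrics].agg(["count", "mean", "std"])
               if len(df) else pd.DataFrame())
    tests = {}
    if compare is not None and len(df):
        g1 = df[(df.year == compare[0]) & df.complete]
        g2 = df[(df.year == compare[1]) & df.complete]
        for m in metrics:
            a, b = g1[m].dropna(), g2[m].dropna()
            if len(a) == 0 or len(b) == 0:
                warnings.warn(f"no complete trips in one group; skipping test for {m}")
                continue
            tests[m] = rank_sum_test(a, b)
    return {"table": df, "summary": summary, "tests": tests}


def distance_to_polygon(lons, lats, polygon: BaseGeometry,
                        projection: LocalProjection) -> np.ndarray:
    """Closest distance (km) from each point to a lon/lat polygon, zero for
    points inside or on the boundary.  Both the points and the polygon are
    projected into the local planar frame before measuring."""
    if polygon.is_empty:
        raise ValueError("empty polygon")
    poly = projection.project_geometry(polygon)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if not poly.is_valid or poly.is_empty:
            raise ValueError("polygon invalid after cleaning")
    x, y = projection.forward(np.asarray(lons, dtype=float),
                              np.asarray(lats, dtype=float))
    pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
    out = np.empty(len(pts))
    for i, (px, py) in enumerate(pts):
        p = Point(px, py)
        out[i] = 0.0 if poly.covers(p) else p.distance(poly)
    return out


def write_trips_geojson(path, trips: list[Trip]) -> None:
    from shapely.geometry import LineString

    from .geo import write_geojson

    geoms, props = [], []
    for tr in trips:
        if len(tr.fixes) < 2:
            continue
        geoms.append(LineString(np.column_stack([tr.fixes.lon, tr.fixes.lat])))
        props.append({"bird_id": tr.bird_id, "complete": tr.complete,
                      "duration_h": tr.duration_h,
                      "path_length_km": tr.path_length_km,
                      "max_distance_km": tr.max_distance_km})
    write_geojson(path, geoms, props)
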