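"""Kernel utilization distributions and habitat overlap.

The utilization distribution (UD) is a bivariate Gaussian product-kernel
density of foraging/resting positions on a regular grid in the local planar
frame (km).  The default smoothing parameter is the bivariate reference
("ad-hoc") rule

    h = sigma * n**(-1/6),   sigma = sqrt((var_x + var_y) / 2),

the convention of classical home-range software.  Core-use areas are volume
contours: the smallest set of grid cells containing a stated fraction of the
UD mass (75% by default), polygonised for overlap arithmetic with other
kernels or with a bathymetric shelf-break band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPolygon, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union


def adhoc_bandwidth(points: np.ndarray) -> float:
    """Reference-rule bandwidth h = sigma * n**(-1/6) for bivariate data."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    sigma = np.sqrt((pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)) / 2.0)
    return float(sigma * n ** (-1.0 / 6.0))


@dataclass
class UtilizationDistribution:
    x: np.ndarray  # cell-centre coordinates, km
    y: np.ndarray
    density: np.ndarray  # [ny, nx], probability per km^2
    bandwidth: float
    n_points: int

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def to_frame(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": X.ravel(), "y": Y.ravel(),
                             "density": self.density.ravel()})


@dataclass
class VolumeContour:
    level: float
    polygons: BaseGeometry = field(repr=False)
    area_km2: float
    contained_mass: float
    threshold_density: float


@dataclass
class OverlapReport:
    area_a_km2: float
    area_b_km2: float
    area_intersection_km2: float
    area_union_km2: float
    pct_of_a: float
    pct_of_b: float
    pct_of_union: float


def kde_ud(points, bandwidth: float | None = None, grid_size: int = 200,
           pad_bandwidths: float = 3.0) -> UtilizationDistribution:
    """Gaussian kernel UD of planar points (km) on a regular grid.

    The grid spans the point bounding box padded by ``pad_bandwidths`` times
    the bandwidth; the density is renormalised to integrate to one on the
    grid.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar km coordinates")
    if len(pts) < 5:
        raise ValueError("need at least 5 points for a kernel UD")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points identical; supply a minimum bandwidth "
                         "or jitter the positions")
    h = adhoc_bandwidth(pts) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pad = pad_bandwidths * h
    x = np.linspace(pts[:, 0].min() - pad, pts[:, 0].max() + pad, grid_size)
    y = np.linspace(pts[:, 1].min() - pad, pts[:, 1].max() + pad, grid_size)
    # separable kernel: density = Ky^T @ Kx summed over points
    kx = np.exp(-0.5 * ((x[None, :] - pts[:, 0][:, None]) / h) ** 2)
    ky = np.exp(-0.5 * ((y[None, :] - pts[:, 1][:, None]) / h) ** 2)
    dens = (ky.T @ kx) / (len(pts) * 2.0 * np.pi * h * h)
    cell = (x[1] - x[0]) * (y[1] - y[0])
    dens /= dens.sum() * cell
    return UtilizationDistribution(x=x, y=y, density=dens, bandwidth=h,
                                   n_points=len(pts))


def _mask_to_polygons(mask: np.ndarray, x: np.ndarray, y: np.ndarray) -> BaseGeometry:
    """Union of cell rectangles for True cells, merging row runs first."""
    dx = x[1] - x[0]
    dy = y[1] - y[0]
    rects = []
    for i in np.flatnonzero(mask.any(axis=1)):
        row = mask[i]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            rects.append(box(x[s] - dx / 2, y[i] - dy / 2,
                             x[e - 1] + dx / 2, y[i] + dy / 2))
    if not rects:
        return MultiPolygon([])
    geom = unary_union(rects)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def volume_contour(ud: UtilizationDistribution, level: float = 0.75) -> VolumeContour:
    """Smallest grid-cell region containing ``level`` of the UD mass.

    Cells are accumulated in order of decreasing density until the target
    mass is reached, then polygonised; the contained mass therefore exceeds
    the level by at most one cell's mass.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    cmass = np.cumsum(flat[order]) * ud.cell_area
    k = int(np.searchsorted(cmass, level)) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.density.shape)
    geom = _mask_to_polygons(mask, ud.x, ud.y)
    return VolumeContour(level=level, polygons=geom, area_km2=float(geom.area),
                         contained_mass=float(cmass[k - 1]),
                         threshold_density=float(flat[order[k - 1]]))


def _as_geometry(obj) -> BaseGeometry:
    if isinstance(obj, VolumeContour):
        return obj.polygons
    if isinstance(obj, BaseGeometry):
        return obj
    raise TypeError(f"expected VolumeContour or shapely geometry, got {type(obj)}")


def overlap(a, b) -> OverlapReport:
    """Overlap between two regions (volume contours or habitat polygons).

    All three percentage conventions are reported — relative to A, to B and
    to the union — because "percentage of overlap" is ambiguous; the caller
    picks the denominator appropriate to the question.
    """
    ga, gb = _as_geometry(a), _as_geometry(b)
    for name, g in (("A", ga), ("B", gb)):
        if not g.is_valid:
            g = g.buffer(0)
        if not g.is_valid:
            raise ValueError(f"geometry {name} invalid after cleaning")
    inter = ga.intersection(gb).area
    union = ga.union(gb).area
    return OverlapReport(
        area_a_km2=float(ga.area), area_b_km2=float(gb.area),
        area_intersection_km2=float(inter), area_union_km2=float(union),
        pct_of_a=100.0 * inter / ga.area if ga.area else 0.0,
        pct_of_b=100.0 * inter / gb.area if gb.area else 0.0,
        pct_of_union=100.0 * inter / union if union else 0.0,
    )


def shelf_band_from_isobaths(iso_a: LineString, iso_b: LineString) -> Polygon:
    """Close two roughly parallel isobath polylines into a band polygon by
    joining their endpoints."""
    coords = list(iso_a.coords) + list(iso_b.coords)[::-1]
    band = Polygon(coords)
    if not band.is_valid:
        band = band.buffer(0)
    if band.is_empty or not band.is_valid:
        raise ValueError("could not build a valid band from the isobaths")
    return band


def bin_sightings(lons, counts, bin_width: float = 0.1,
                  isobath_lons: dict[str, float] | None = None) -> pd.DataFrame:
    """Sum at-sea sighting counts into longitude bins.

    ``isobath_lons`` (e.g. ``{"500m": -19.5, "1500m": -18.9}``) adds one
    column per isobath with the bin-centre offset in degrees from that
    isobath, for plotting counts relative to the shelf break.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lons = np.asarray(lons, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if lons.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_centre", "count"])
    idx = np.floor(lons / bin_width).astype(int)
    df = (pd.DataFrame({"bin": idx, "count": counts})
          .groupby("bin", as_index=False)["count"].sum())
    full = np.arange(df.bin.min(), df.bin.max() + 1)
    df = df.set_index("bin").reindex(full, fill_value=0.0).reset_index()
    df["bin_left"] = df.bin * bin_width
    df["bin_centre"] = df.bin_left + bin_width / 2.0
    out = df[["bin_left", "bin_centre", "count"]]
    if isobath_lons:
        for name, lon0 in isobath_lons.items():
            out = out.assign(**{f"offset_{name}_deg": out.bin_centre - lon0})
    return out
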