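"""Synthetic inputs for the whole pipeline.

Generates every data stream the analysis consumes — GPS fixes of
central-place foraging trips, time-depth-recorder series, zooplankton count
compositions for at-sea hauls and gular-pouch (chick meal) loads, chick mass
series, adult morphometrics, sea-ice concentration grids and ice-edge
polygons — with the statistical structure the downstream estimators assume.

Defaults describe a small planktivorous Arctic seabird breeding on the East
Greenland coast: birds commute eastward from the colony to foraging grounds
~90–110 km away over the shelf break, fixes every 15 min, ~270 dives per
24 h to ~17–21 m lasting ~55–60 s, and two distinct zooplankton communities
(continental shelf vs shelf break / open ocean) dominated by *Calanus*
copepods.  Every generator draws from its own deterministic substream of the
scenario seed, so adding a generator never perturbs the others, and every
generator emits its ground truth alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .geo import LocalProjection, write_geojson

# Stable substream ids: appending new generators must not renumber these.
_STREAMS = {
    "tracks": 1,
    "dives": 2,
    "zoo": 3,
    "pouch": 4,
    "growth": 5,
    "morph": 6,
    "seaice": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


# Taxon-group universe shared by pouch and at-sea compositions.
TAXA = (
    "C. hyperboreus",
    "C. glacialis",
    "C. finmarchicus",
    "Calanus CI-CIII",
    "Small copepods",
    "Paraeuchaeta spp",
    "Oithona spp",
    "Apherusa glacialis",
    "Gammarus spp",
    "Onisimus spp",
    "Thysanoessa spp",
    "Themisto spp",
    "Decapod larvae",
    "Fish",
    "Limacina helicina",
    "Nauplius larvae",
    "Tunicates",
    "Echinodermata larvae",
    "Unknown",
)

# At-sea community profiles (% mean relative abundance) by bathymetric
# stratum; zero for taxa never caught in the net.
_AT_SEA_RA = {
    "continental_shelf": {
        "C. hyperboreus": 3.9, "C. glacialis": 6.3, "C. finmarchicus": 4.8,
        "Calanus CI-CIII": 38.6, "Small copepods": 16.1, "Oithona spp": 8.6,
        "Themisto spp": 0.1, "Limacina helicina": 1.1, "Nauplius larvae": 4.3,
        "Tunicates": 6.2, "Echinodermata larvae": 5.9, "Unknown": 4.2,
    },
    "shelf_break": {
        "C. hyperboreus": 0.4, "C. glacialis": 1.8, "C. finmarchicus": 7.6,
        "Calanus CI-CIII": 26.4, "Small copepods": 36.6, "Oithona spp": 11.0,
        "Themisto spp": 0.1, "Limacina helicina": 0.1, "Nauplius larvae": 6.2,
        "Tunicates": 4.1, "Echinodermata larvae": 0.6, "Unknown": 5.2,
    },
    "open_ocean": {
        "C. hyperboreus": 0.2, "C. glacialis": 0.6, "C. finmarchicus": 10.1,
        "Calanus CI-CIII": 15.5, "Small copepods": 42.4, "Oithona spp": 10.5,
        "Themisto spp": 0.1, "Nauplius larvae": 2.8, "Tunicates": 7.3,
        "Echinodermata larvae": 0.3, "Unknown": 10.2,
    },
}

# Gular-pouch load profiles per year: (mean %, SD %) per taxon.
_POUCH_RA = {
    2012: {
        "C. hyperboreus": (65.3, 28.6), "C. glacialis": (15.5, 9.2),
        "C. finmarchicus": (4.2, 4.0), "Paraeuchaeta spp": (0.01, 0.05),
        "Apherusa glacialis": (8.7, 26.4), "Gammarus spp": (0.5, 1.9),
        "Onisimus spp": (0.3, 0.7), "Thysanoessa spp": (4.2, 13.8),
        "Themisto spp": (1.1, 1.6), "Decapod larvae": (0.01, 0.03),
        "Fish": (0.03, 0.1), "Limacina helicina": (0.2, 0.4),
        "Unknown": (0.01, 0.02),
    },
    2014: {
        "C. hyperboreus": (47.0, 17.6), "C. glacialis": (34.1, 12.8),
        "C. finmarchicus": (9.0, 6.7), "Paraeuchaeta spp": (0.1, 0.3),
        "Apherusa glacialis": (0.1, 0.3), "Thysanoessa spp": (4.7, 11.4),
        "Themisto spp": (4.2, 5.2), "Decapod larvae": (0.1, 0.3),
        "Fish": (0.2, 0.3), "Limacina helicina": (0.1, 0.4),
        "Unknown": (0.1, 0.3),
    },
}

STRATA = ("continental_shelf", "shelf_break", "open_ocean")


def _normalised_profile(raw: dict[str, float]) -> dict[str, float]:
    total = float(sum(raw.values()))
    if total <= 0:
        raise ValueError("profile must have positive total abundance")
    return {t: raw.get(t, 0.0) / total for t in TAXA}


@dataclass
class ScenarioConfig:
    """Parameters of one simulated field season.

    Distances in km, speeds in km/h, depths in m, durations in s, masses
    in g.  ``community_profiles`` maps stratum -> taxon relative-abundance
    vector (sums to 1); ``pouch_profiles`` maps year -> taxon -> (mean, SD)
    relative abundance as proportions.
    """

    seed: int = 0
    n_birds: int = 6
    fix_interval_min: float = 15.0
    commute_speed_kmh: float = 45.0
    forage_speed_max_kmh: float = 10.0
    target_distance_km: float = 100.0
    target_distance_sd_km: float = 26.0
    forage_spread_km: float = 0.6
    n_dives_per_day: int = 270
    dive_depth_mean_m: float = 19.0
    dive_depth_sd_m: float = 4.0
    dive_duration_mean_s: float = 57.0
    dive_duration_sd_s: float = 6.0
    dive_sampling_interval_s: int = 1
    community_profiles: dict = field(default_factory=dict)
    pouch_profiles: dict = field(default_factory=dict)
    dirichlet_concentration: float = 50.0
    growth_intercept_g: float = 21.0
    growth_slope_g_per_day: float = 6.0
    chick_sd_g: float = 6.0
    resid_sd_g: float = 5.0
    ice_edge_distance_km: float = 23.0
    colony_lon: float = -21.583
    colony_lat: float = 70.733

    def __post_init__(self):
        if not self.community_profiles:
            self.community_profiles = {
                s: _normalised_profile(p) for s, p in _AT_SEA_RA.items()
            }
        else:
            self.community_profiles = {
                s: _normalised_profile(p) for s, p in self.community_profiles.items()
            }
        if not self.pouch_profiles:
            self.pouch_profiles = {
                yr: {t: (m / 100.0, s / 100.0) for t, (m, s) in prof.items()}
                for yr, prof in _POUCH_RA.items()
            }
        if self.n_birds <= 0:
            raise ValueError("n_birds must be positive")
        if self.fix_interval_min <= 0:
            raise ValueError("fix_interval_min must be positive")
        if self.commute_speed_kmh <= 0 or self.forage_speed_max_kmh <= 0:
            raise ValueError("speeds must be positive")
        if self.target_distance_km <= 0:
            raise ValueError("target_distance_km must be positive")
        if self.dive_depth_mean_m < 0 or self.dive_depth_sd_m < 0:
            raise ValueError("dive depth parameters must be non-negative")
        for sd in (self.target_distance_sd_km, self.dive_duration_sd_s,
                   self.chick_sd_g, self.resid_sd_g):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.dive_sampling_interval_s not in (1, 2, 4):
            raise ValueError("dive_sampling_interval_s must be 1, 2 or 4")
        for s, prof in self.community_profiles.items():
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                raise ValueError(f"profile for {s} does not sum to 1")

    @property
    def colony(self) -> tuple[float, float]:
        return (self.colony_lon, self.colony_lat)

    def projection(self) -> LocalProjection:
        return LocalProjection(self.colony_lon, self.colony_lat)


# ---------------------------------------------------------------------------
# GPS tracks

def gen_tracks(config: ScenarioConfig, n_birds: int | None = None,
               year: int = 2012,
               start: str = "2012-07-20T00:00:00") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one commute–forage–commute foraging trip per bird.

    Each track starts and ends at the colony, flies out at commuting speed
    on a near-eastward bearing to an apex drawn around ``target_distance_km``,
    forages/rests in a tight low-speed cluster at the apex, and commutes
    straight back.  Returns ``(fixes, truth)``: fixes with columns
    ``bird_id, t, lon, lat, year`` and per-trip ground truth with the apex
    distance and timing.
    """
    n_birds = config.n_birds if n_birds is None else int(n_birds)
    if n_birds <= 0:
        raise ValueError("n_birds must be positive")
    rng = _rng(config.seed, "tracks")
    rng = np.random.default_rng(rng.integers(2**31) + year)  # per-year substream
    proj = config.projection()
    dt_h = config.fix_interval_min / 60.0
    t0 = pd.Timestamp(start)

    fix_rows, truth_rows = [], []
    for b in range(n_birds):
        bird_id = f"{year}_B{b:02d}"
        apex = max(25.0, rng.normal(config.target_distance_km,
                                    config.target_distance_sd_km))
        ang = rng.normal(0.0, np.radians(8.0))  # bearing scatter about due east
        u = np.array([np.cos(ang), np.sin(ang)])
        step = config.commute_speed_kmh * dt_h
        n_out = max(1, int(np.ceil(apex / step)))
        out = np.linspace(step, apex, n_out)[:, None] * u
        apex_xy = out[-1]
        n_forage = max(4, int(round(rng.uniform(20.0, 28.0) / dt_h)))
        forage = apex_xy + rng.normal(0.0, config.forage_spread_km,
                                      size=(n_forage, 2))
        back_from = forage[-1]
        d_back = float(np.hypot(*back_from))
        n_back = max(1, int(np.ceil(d_back / step)))
        frac = np.linspace(1.0, 0.0, n_back + 1)[1:]
        back = back_from[None, :] * frac[:, None]
        back[-1] = (0.0, 0.0)
        xy = np.vstack([[(0.0, 0.0)], out, forage, back])
        t_start = t0 + pd.Timedelta(hours=float(b) * 36.0)
        times = t_start + pd.to_timedelta(np.arange(len(xy)) * dt_h, unit="h")
        lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
        fix_rows.append(pd.DataFrame({
            "bird_id": bird_id, "t": times, "lon": lon, "lat": lat, "year": year,
        }))
        dists = np.hypot(xy[:, 0], xy[:, 1])
        truth_rows.append({
            "bird_id": bird_id, "year": year,
            "apex_km": float(dists.max()),
            "n_fixes": int(len(xy)),
            "forage_start": int(1 + n_out),
            "forage_end": int(n_out + n_forage),
            "t_start": times[0], "t_end": times[-1],
        })
    fixes = pd.concat(fix_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return fixes, truth


def gen_ice_polygon(config: ScenarioConfig,
                    edge_distance_km: float | None = None) -> Polygon:
    """A compact-ice polygon whose western edge sits ``edge_distance_km``
    beyond the nominal foraging grounds (lon/lat coordinates)."""
    d = config.ice_edge_distance_km if edge_distance_km is None else float(edge_distance_km)
    proj = config.projection()
    x0 = config.target_distance_km + d
    corners = [(x0, -400.0), (x0 + 300.0, -400.0),
               (x0 + 300.0, 400.0), (x0, 400.0)]
    lonlat = [tuple(np.asarray(proj.inverse(x, y), dtype=float)) for x, y in corners]
    return Polygon(lonlat)


# ---------------------------------------------------------------------------
# Dive records

def gen_dives(config: ScenarioConfig, hours: float = 24.0,
              sampling_interval_s: int | None = None,
              tag_model: str = "G5") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a square-wave time-depth record plus its ground-truth dives.

    The number of dives is Poisson around ``n_dives_per_day`` scaled to the
    record length; dive depths and durations are normal around the
    configured means.  Surface samples carry sub-decimetre sensor noise.
    Returns ``(series, truth)``: series with columns ``t_s, depth_m,
    tag_model`` and truth with ``start_s, end_s, max_depth_m, duration_s``.
    """
    dt = config.dive_sampling_interval_s if sampling_interval_s is None else int(sampling_interval_s)
    if dt not in (1, 2, 4):
        raise ValueError("sampling interval must be 1, 2 or 4 s")
    if config.n_dives_per_day < 0:
        raise ValueError("n_dives_per_day must be non-negative")
    rng = _rng(config.seed, "dives")
    span = float(hours) * 3600.0
    n = int(rng.poisson(config.n_dives_per_day * hours / 24.0))
    t = np.arange(0.0, span, float(dt))
    depth = np.abs(rng.normal(0.0, 0.15, size=t.size))  # surface noise, < 0.6 m

    truth_rows = []
    if n > 0:
        dur = np.clip(rng.normal(config.dive_duration_mean_s,
                                 config.dive_duration_sd_s, size=n), 12.0, None)
        dmax = np.clip(rng.normal(config.dive_depth_mean_m,
                                  config.dive_depth_sd_m, size=n), 5.0, None)
        busy = dur.sum()
        if busy >= 0.9 * span:
            raise ValueError("dive load exceeds record span; reduce n_dives_per_day")
        gaps = rng.dirichlet(np.ones(n + 1)) * (span - busy)
        starts = np.cumsum(gaps[:-1]) + np.concatenate([[0.0], np.cumsum(dur[:-1])])
        for s, d, z in zip(starts, dur, dmax):
            sel = (t >= s) & (t < s + d)
            depth[sel] = z + rng.normal(0.0, 0.1, size=sel.sum())
            truth_rows.append({"start_s": float(s), "end_s": float(s + d),
                               "max_depth_m": float(z), "duration_s": float(d)})
    series = pd.DataFrame({"t_s": t, "depth_m": depth, "tag_model": tag_model})
    truth = pd.DataFrame(truth_rows,
                         columns=["start_s", "end_s", "max_depth_m", "duration_s"])
    return series, truth


# ---------------------------------------------------------------------------
# Zooplankton compositions

def gen_zoo_samples(config: ScenarioConfig, stratum: str, n_samples: int,
                    mean_total_count: int = 400,
                    haul_depth_m: float = 50.0,
                    net_diameter_m: float = 0.57,
                    year: int = 2014) -> pd.DataFrame:
    """At-sea haul count compositions, Dirichlet-multinomial around the
    stratum community profile.  Long format, one row per sample x taxon."""
    if stratum not in config.community_profiles:
        raise ValueError(f"unknown stratum {stratum!r}; "
                         f"expected one of {sorted(config.community_profiles)}")
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    rng = _rng(config.seed, "zoo")
    stratum_key = zlib.crc32(stratum.encode()) % 10000  # stable across processes
    rng = np.random.default_rng(rng.integers(2**31) + stratum_key + n_samples)
    profile = config.community_profiles[stratum]
    p = np.array([profile[t] for t in TAXA])
    nonzero = p > 0
    rows = []
    for i in range(int(n_samples)):
        ra = np.zeros_like(p)
        ra[nonzero] = rng.dirichlet(config.dirichlet_concentration * p[nonzero])
        total = max(1, int(rng.poisson(mean_total_count)))
        counts = rng.multinomial(total, ra)
        sid = f"{stratum}_{i:02d}"
        for taxon, c in zip(TAXA, counts):
            rows.append({"sample_id": sid, "source": "at_sea", "year": year,
                         "stratum": stratum, "taxon": taxon, "count": int(c),
                         "haul_depth": haul_depth_m, "net_diameter": net_diameter_m})
    cols = ["sample_id", "source", "year", "stratum", "taxon", "count",
            "haul_depth", "net_diameter"]
    return pd.DataFrame(rows, columns=cols)


def gen_pouch_samples(config: ScenarioConfig, year: int, n_samples: int,
                      mean_total_count: int = 300) -> pd.DataFrame:
    """Gular-pouch (chick meal) count compositions for one year.

    Per-sample relative abundances are drawn taxon-wise from normals around
    the year profile means/SDs, clipped at zero and renormalised, then
    converted to counts."""
    if year not in config.pouch_profiles:
        raise ValueError(f"no pouch profile for year {year}")
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    rng = _rng(config.seed, "pouch")
    rng = np.random.default_rng(rng.integers(2**31) + year + n_samples)
    prof = config.pouch_profiles[year]
    means = np.array([prof.get(t, (0.0, 0.0))[0] for t in TAXA])
    sds = np.array([prof.get(t, (0.0, 0.0))[1] for t in TAXA])
    rows = []
    for i in range(int(n_samples)):
        ra = np.clip(rng.normal(means, sds), 0.0, None)
        if ra.sum() <= 0:
            ra = means.copy()
        ra /= ra.sum()
        total = max(1, int(rng.poisson(mean_total_count)))
        counts = rng.multinomial(total, ra)
        sid = f"gp{year}_{i:02d}"
        for taxon, c in zip(TAXA, counts):
            rows.append({"sample_id": sid, "source": "gular_pouch", "year": year,
                         "stratum": "none", "taxon": taxon, "count": int(c),
                         "haul_depth": np.nan, "net_diameter": np.nan})
    cols = ["sample_id", "source", "year", "stratum", "taxon", "count",
            "haul_depth", "net_diameter"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Chick growth and adult morphometrics

def gen_growth(config: ScenarioConfig, n_chicks: int,
               years: tuple[int, ...] = (2012, 2014),
               year_effect_g: float = 0.0) -> pd.DataFrame:
    """Chick mass series over the linear growth window (age 4-14 d, every
    second day): mass = intercept + slope*age + year effect + chick random
    intercept + residual noise."""
    if n_chicks < 1:
        raise ValueError("n_chicks must be >= 1")
    rng = _rng(config.seed, "growth")
    ages = np.arange(4, 15, 2)
    rows = []
    for c in range(int(n_chicks)):
        year = years[c % len(years)]
        b = rng.normal(0.0, config.chick_sd_g)
        eff = year_effect_g if year == years[-1] and len(years) > 1 else 0.0
        mass = (config.growth_intercept_g + config.growth_slope_g_per_day * ages
                + b + eff + rng.normal(0.0, config.resid_sd_g, size=ages.size))
        for a, m in zip(ages, mass):
            rows.append({"chick_id": f"c{c:03d}", "year": year,
                         "age": int(a), "mass": float(m)})
    return pd.DataFrame(rows)


def gen_morphometrics(config: ScenarioConfig, n_per_year: dict[int, int],
                      year_shift_g: float = 0.0,
                      noise_sd_g: float = 8.0) -> pd.DataFrame:
    """Adult mass/wing/head-bill tables; mass is linear in the two skeletal
    size measures plus an optional year shift (injected condition effect)."""
    rng = _rng(config.seed, "morph")
    years = sorted(n_per_year)
    rows = []
    for yi, year in enumerate(years):
        n = int(n_per_year[year])
        if n < 1:
            raise ValueError("need at least one bird per year")
        wing = rng.normal(121.0, 3.0, size=n)
        headbill = rng.normal(45.0, 1.5, size=n)
        shift = year_shift_g if yi == len(years) - 1 and len(years) > 1 else 0.0
        mass = (150.0 + 2.0 * (wing - 121.0) + 3.0 * (headbill - 45.0)
                + shift + rng.normal(0.0, noise_sd_g, size=n))
        for j in range(n):
            rows.append({"bird_id": f"a{year}_{j:03d}", "year": year,
                         "mass": float(mass[j]), "wing": float(wing[j]),
                         "headbill": float(headbill[j])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sea-ice concentration

def gen_sic_grids(config: ScenarioConfig, dates, mean_sic_pct: float = 10.0,
                  sd_pct: float = 5.0, nx: int = 12, ny: int = 16,
                  spacing_km: float = 12.5) -> pd.DataFrame:
    """Daily gridded sea-ice concentration fields (long CSV schema:
    date, lon, lat, sic) on a regular local grid around the colony."""
    rng = _rng(config.seed, "seaice")
    proj = config.projection()
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing_km
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing_km
    X, Y = np.meshgrid(xs, ys)
    lon, lat = proj.inverse(X.ravel(), Y.ravel())
    rows = []
    for d in pd.to_datetime(list(dates)):
        sic = np.clip(rng.normal(mean_sic_pct, sd_pct, size=lon.size), 0.0, 100.0)
        rows.append(pd.DataFrame({"date": d, "lon": lon, "lat": lat, "sic": sic}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Scenario writer

def write_scenario(config: ScenarioConfig, outdir) -> dict[str, str]:
    """Write a full synthetic field season to ``outdir``.

    Emits CSVs matching the reader schemas of the analysis modules, GeoJSON
    for the colony point and ice polygon, and a JSON ground-truth sidecar.
    Byte-identical for identical configs (same seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = str(p)

    fixes12, truth12 = gen_tracks(config, year=2012, start="2012-07-20T00:00:00")
    fixes14, truth14 = gen_tracks(config, year=2014, start="2014-07-22T00:00:00")
    _save(pd.concat([fixes12, fixes14], ignore_index=True), "gps_fixes.csv")

    series, dive_truth = gen_dives(config)
    _save(series, "tdr.csv")

    zoo = pd.concat([gen_zoo_samples(config, s, 10 if s == "continental_shelf" else 5)
                     for s in STRATA], ignore_index=True)
    _save(zoo, "zoo_counts.csv")
    pouch = pd.concat([gen_pouch_samples(config, y, 20) for y in (2012, 2014)],
                      ignore_index=True)
    _save(pouch, "pouch_counts.csv")
    _save(gen_growth(config, 53), "chick_growth.csv")
    _save(gen_morphometrics(config, {2012: 65, 2014: 120}), "adult_morphs.csv")

    ice = gen_ice_polygon(config)
    write_geojson(outdir / "ice.geojson", [ice], [{"kind": "pack_ice_ge80pct"}])
    write_geojson(outdir / "colony.geojson",
                  [Point(config.colony_lon, config.colony_lat)],
                  [{"kind": "colony"}])
    paths["ice.geojson"] = str(outdir / "ice.geojson")
    paths["colony.geojson"] = str(outdir / "colony.geojson")

    truth = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if not isinstance(v, dict)},
        "trips": pd.concat([truth12, truth14], ignore_index=True)
                   .assign(t_start=lambda d: d.t_start.astype(str),
                           t_end=lambda d: d.t_end.astype(str))
                   .to_dict(orient="records"),
        "dives": dive_truth.to_dict(orient="records"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth.json"] = str(outdir / "truth.json")
    return paths
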