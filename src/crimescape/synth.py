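"""Synthetic study area and event-stream generator.

Emulates the four inputs of the real-data pipeline — a neighborhood
tessellation grouped into contiguous municipalities, a municipal population
table, a highway polyline and a dated, geolocated casualty table — with the
statistical structure the downstream analysis assumes:

* per-neighborhood homogeneous-in-space, inhomogeneous-in-time Poisson
  event counts, ``rate = base_rate · hotspot(k) · wave(week)``;
* planted same-week co-occurring neighborhood pairs (for network recovery
  tests);
* an optional fraction of events relocated to within a half-width of the
  highway (for proximity analyses).

The default city is a rectangular grid: adjacency is then analytically
known, so contiguity-graph behaviour can be tested exactly.  Coordinates
are generated directly in lon/lat on a small patch near (−100.3, 25.7) so
that spherical-distance and projection code paths run under realistic
latitudes.  A single seed drives all randomness; each stage draws from a
deterministically spawned child stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd
from shapely import contains as _contains, points as _points
from shapely.geometry import LineString, Polygon, box

from .errors import ConfigError
from .geoio import (KM_PER_DEG, HighwaySet, LocalProjection, MunicipalityTable,
                    NeighborhoodMap)

GRID_ORIGIN = (-100.35, 25.65)  # SW corner (lon, lat) of the default patch
DEFAULT_START = _date(2011, 1, 3)  # a Monday


@dataclass
class CityConfig:
    """Parameters of the synthetic city and its event stream.

    Rates are events per neighborhood per week.  ``wave`` is a
    piecewise-constant temporal multiplier: a list of any length, expanded
    to one block per equal span of weeks (length ``n_weeks`` applies
    element-wise).  ``planted_pairs`` entries are
    ``(neighborhood, neighborhood, n_weeks)`` where neighborhoods may be
    row-major cell indices or string ids; each pair is forced to receive at
    least one event in both members in ``n_weeks`` distinct weeks.
    ``highway_bias`` is the fraction of events relocated to within
    ``highway_halfwidth_km`` of the highway.
    """

    n_rows: int = 10
    n_cols: int = 10
    cell_size_km: float = 1.0
    n_municipalities: int = 4
    populations: list[float] = field(default_factory=lambda: [250_000.0] * 4)
    base_rate: float = 0.05
    hotspot_ids: list[int] = field(default_factory=list)
    hotspot_multiplier: float = 1.0
    wave: list[float] | None = None
    planted_pairs: list[tuple] = field(default_factory=list)
    highway_path: list[tuple[float, float]] | None = None
    highway_bias: float = 0.0
    highway_halfwidth_km: float = 0.5
    n_weeks: int = 52
    seed: int = 0
    origin: tuple[float, float] = GRID_ORIGIN
    start_date: _date = DEFAULT_START
    casualty_dist: str = "ones"  # or "geometric"
    casualty_p: float = 0.7

    def __post_init__(self):
        n_cells = self.n_rows * self.n_cols
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigError("grid dimensions must be positive")
        if self.n_weeks <= 0:
            raise ConfigError("n_weeks must be positive")
        if len(self.populations) != self.n_municipalities:
            raise ConfigError(
                f"populations has {len(self.populations)} entries for "
                f"{self.n_municipalities} municipalities")
        if any(p <= 0 for p in self.populations):
            raise ConfigError("populations must all be positive")
        if self.n_municipalities > n_cells:
            raise ConfigError("more municipalities than grid cells")
        if self.hotspot_multiplier < 1:
            raise ConfigError("hotspot_multiplier must be >= 1")
        if not 0.0 <= self.highway_bias <= 1.0:
            raise ConfigError("highway_bias must lie in [0, 1]")
        if self.base_rate < 0:
            raise ConfigError("base_rate must be non-negative")
        for h in self.hotspot_ids:
            if not 0 <= h < n_cells:
                raise ConfigError(f"hotspot id {h} outside grid")
        for a, b, w in self.planted_pairs:
            if a == b:
                raise ConfigError("planted pair members must be distinct")
            for v in (a, b):
                if isinstance(v, int) and not 0 <= v < n_cells:
                    raise ConfigError(f"planted pair id {v} outside grid")
            if not 1 <= w <= self.n_weeks:
                raise ConfigError("planted pair n_weeks outside study window")
        if self.wave is not None and any(w < 0 for w in self.wave):
            raise ConfigError("wave multipliers must be non-negative")
        if self.casualty_dist not in ("ones", "geometric"):
            raise ConfigError(f"unknown casualty_dist {self.casualty_dist!r}")


def _municipality_blocks(n_rows: int, n_cols: int, n_mun: int) -> np.ndarray:
    """Assign each cell a municipality id, in contiguous blocks.

    Cells are walked in boustrophedon (snake) order — row by row,
    alternating direction — and split into nearly-equal runs; every run is
    rook-connected, so municipalities are guaranteed contiguous.
    """
    order = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        order.extend(r * n_cols + c for c in cols)
    assignment = np.empty(n_rows * n_cols, dtype=int)
    for m, run in enumerate(np.array_split(np.array(order), n_mun)):
        assignment[run] = m
    return assignment


def cell_id(config: CityConfig, cell_index: int) -> str:
    """Stable neighborhood id ("municipality::name") of a grid cell."""
    mun = _municipality_blocks(config.n_rows, config.n_cols,
                               config.n_municipalities)[cell_index]
    return f"M{mun:02d}::N{cell_index:04d}"


def generate_city(config: CityConfig) -> tuple[NeighborhoodMap, MunicipalityTable, HighwaySet]:
    """Build the tessellation, population table and highway for *config*.

    The tessellation is gap-free (n_rows × n_cols rectangles), each cell in
    exactly one contiguous municipality block.  The highway (a default
    corner-to-corner diagonal when ``highway_path`` is None) is clipped to
    the city bounding box.  Fully deterministic.
    """
    lon0, lat0 = config.origin
    dlat = config.cell_size_km / KM_PER_DEG
    dlon = config.cell_size_km / (KM_PER_DEG * math.cos(math.radians(lat0)))
    mun_of = _municipality_blocks(config.n_rows, config.n_cols, config.n_municipalities)

    recs = []
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            k = r * config.n_cols + c
            poly = box(lon0 + c * dlon, lat0 + r * dlat,
                       lon0 + (c + 1) * dlon, lat0 + (r + 1) * dlat)
            recs.append((f"N{k:04d}", f"M{mun_of[k]:02d}", poly))
    nmap = NeighborhoodMap.from_polygons(recs)

    pops = MunicipalityTable({f"M{m:02d}": float(config.populations[m])
                              for m in range(config.n_municipalities)})

    city_box = box(lon0, lat0,
                   lon0 + config.n_cols * dlon, lat0 + config.n_rows * dlat)
    if config.highway_path is not None:
        path = LineString(config.highway_path)
    else:
        # diagonal crossing the whole city through its centre
        path = LineString([(lon0, lat0),
                           (lon0 + config.n_cols * dlon, lat0 + config.n_rows * dlat)])
    clipped = path.intersection(city_box)
    if clipped.is_empty:
        raise ConfigError("highway_path does not intersect the city bounding box")
    if clipped.geom_type == "LineString":
        lines = [list(clipped.coords)]
    else:  # MultiLineString after clipping
        lines = [list(g.coords) for g in clipped.geoms]
    highways = HighwaySet([[(float(x), float(y)) for x, y in l] for l in lines])
    return nmap, pops, highways


def _wave_per_week(config: CityConfig) -> np.ndarray:
    if config.wave is None:
        return np.ones(config.n_weeks)
    w = np.asarray(config.wave, dtype=float)
    if len(w) == config.n_weeks:
        return w
    # expand to piecewise-constant blocks of equal width
    idx = (np.arange(config.n_weeks) * len(w)) // config.n_weeks
    return w[idx]


def _sample_in_polygon(poly: Polygon, rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform points inside *poly* via bbox rejection; (n, 2) lon/lat."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(n - got, 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        mask = _contains(poly, _points(np.column_stack([xs, ys])))
        take = min(int(mask.sum()), n - got)
        sel = np.flatnonzero(mask)[:take]
        out[got:got + take, 0] = xs[sel]
        out[got:got + take, 1] = ys[sel]
        got += take
    return out


def _relocate_near_highway(lonlat: np.ndarray, highways: HighwaySet,
                           halfwidth_km: float, rng: np.random.Generator) -> np.ndarray:
    """Resample points to lie within *halfwidth_km* of the highway."""
    proj = LocalProjection.for_bounds(*highways.bounds())
    segs = []
    for line in highways.polylines:
        arr = np.asarray(line, float)
        x, y = proj.to_xy(arr[:, 0], arr[:, 1])
        xy = np.column_stack([x, y])
        for i in range(len(xy) - 1):
            segs.append((xy[i], xy[i + 1]))
    lengths = np.array([np.hypot(*(b - a)) for a, b in segs])
    w = lengths / lengths.sum() if lengths.sum() > 0 else np.full(len(segs), 1 / len(segs))
    n = len(lonlat)
    pick = rng.choice(len(segs), size=n, p=w)
    t = rng.random(n)
    r = rng.uniform(0.0, halfwidth_km * 1000.0, n)
    theta = rng.uniform(0.0, 2 * math.pi, n)
    out = np.empty_like(lonlat)
    for i, s in enumerate(pick):
        a, b = segs[s]
        base = a + t[i] * (b - a)
        p = base + r[i] * np.array([math.cos(theta[i]), math.sin(theta[i])])
        lon, lat = proj.to_lonlat(p[0], p[1])
        out[i] = (lon, lat)
    return out


def _planted_weeks(config: CityConfig, rng: np.random.Generator) -> list[tuple[str, str, np.ndarray]]:
    """Choose distinct weeks for each planted pair, avoiding reuse across
    pairs while weeks remain, so planted edges are recovered exactly."""
    free = list(range(config.n_weeks))
    rng.shuffle(free)
    chosen = []
    for a, b, nw in config.planted_pairs:
        a_id = cell_id(config, a) if isinstance(a, int) else str(a)
        b_id = cell_id(config, b) if isinstance(b, int) else str(b)
        if len(free) >= nw:
            weeks = np.array([free.pop() for _ in range(nw)])
        else:  # more planted weeks than weeks in the window: sample with reuse
            weeks = rng.choice(config.n_weeks, size=nw, replace=False)
        chosen.append((a_id, b_id, np.sort(weeks)))
    return chosen


def generate_events(city: tuple[NeighborhoodMap, MunicipalityTable, HighwaySet],
                    config: CityConfig) -> pd.DataFrame:
    """Draw the synthetic event table for a generated city.

    Returns a DataFrame with the source schema columns
    ``date, lat, lon, casualties, title, url`` plus bookkeeping columns
    ``neighborhood_id`` (the generating cell; relocation may move the point
    elsewhere) and ``week_index``.
    """
    if config.n_weeks <= 0:
        raise ConfigError("n_weeks must be positive")
    nmap, _pops, highways = city
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_place, rng_cas, rng_plant, rng_hwy = (
        np.random.default_rng(s) for s in ss.spawn(5))

    n_cells = config.n_rows * config.n_cols
    ids = [cell_id(config, k) for k in range(n_cells)]
    mult = np.ones(n_cells)
    for h in config.hotspot_ids:
        mult[h] = config.hotspot_multiplier
    wave = _wave_per_week(config)
    lam = config.base_rate * mult[:, None] * wave[None, :]  # (cells, weeks)
    counts = rng_counts.poisson(lam) if config.base_rate > 0 else np.zeros_like(lam, dtype=int)

    rows: list[tuple[str, int]] = []  # (neighborhood_id, week)
    for k in range(n_cells):
        for w in np.flatnonzero(counts[k]):
            rows.extend([(ids[k], int(w))] * int(counts[k, w]))
    for a_id, b_id, weeks in _planted_weeks(config, rng_plant):
        for w in weeks:
            rows.append((a_id, int(w)))
            rows.append((b_id, int(w)))

    if not rows:
        df = pd.DataFrame(columns=["date", "lat", "lon", "casualties", "title",
                                   "url", "neighborhood_id", "week_index"])
        df["date"] = pd.to_datetime(df["date"])
        return df

    nid = [r[0] for r in rows]
    week = np.array([r[1] for r in rows])
    n = len(rows)

    lonlat = np.empty((n, 2))
    order = np.argsort(np.array(nid), kind="stable")
    i = 0
    while i < len(order):  # sample per neighborhood in id-sorted batches
        j = i
        while j < len(order) and nid[order[j]] == nid[order[i]]:
            j += 1
        batch = order[i:j]
        lonlat[batch] = _sample_in_polygon(nmap[nid[order[i]]].polygon,
                                           rng_place, len(batch))
        i = j

    day = rng_place.integers(0, 7, n)
    start = pd.Timestamp(config.start_date)
    dates = start + pd.to_timedelta(week * 7 + day, unit="D")

    if config.casualty_dist == "ones":
        cas = np.ones(n, dtype=int)
    else:  # zero-truncated geometric on {1, 2, ...}
        cas = rng_cas.geometric(config.casualty_p, n)

    if config.highway_bias > 0 and len(highways) > 0:
        move = rng_hwy.random(n) < config.highway_bias
        if move.any():
            lonlat[move] = _relocate_near_highway(
                lonlat[move], highways, config.highway_halfwidth_km, rng_hwy)

    return pd.DataFrame({
        "date": dates, "lat": lonlat[:, 1], "lon": lonlat[:, 0],
        "casualties": cas,
        "title": "synthetic event", "url": "",
        "neighborhood_id": nid, "week_index": week,
    })
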