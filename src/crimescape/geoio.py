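"""Geospatial containers and I/O.

Everything here works in WGS84 lon/lat degrees.  Metric quantities are
computed either on the sphere (haversine, ``R = 6371.0088`` km) or, where
planar geometry is genuinely needed (areas, point-to-segment distances), in
a local equirectangular projection centred on the data bounding box.  The
study regions this package targets span well under two degrees, so the
projection error is far below the precision of any reported quantity.

Containers
----------
``NeighborhoodMap``
    A tessellation of named polygons grouped into municipalities, with
    per-polygon area (km²) and centroid.
``MunicipalityTable``
    Municipality name → population.
``HighwaySet``
    A list of polylines (ordered lon/lat vertex lists).

Event tables are plain :class:`pandas.DataFrame` objects with columns
``date, lat, lon, casualties`` (plus ``title``/``url`` pass-through
columns and, after mapping, ``neighborhood_id``).
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.strtree import STRtree

from .errors import FormatError, GeometryError

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0  # one degree of latitude

#: Monterrey metropolitan area bounding box (lon_min, lat_min, lon_max, lat_max),
#: the default spatial filter for OSM extracts.
DEFAULT_BBOX = (-100.8421, 25.3217, -99.5650, 26.0346)

EVENT_COLUMNS = ("date", "lat", "lon", "casualties")


# ---------------------------------------------------------------------------
# distances and projection
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection x = R·cosφ₀·λ, y = R·φ (metres).

    Distances are exact along meridians and accurate to O((Δφ)²) elsewhere;
    adequate for sub-degree patches.
    """

    lon0: float
    lat0: float

    @classmethod
    def for_bounds(cls, lon_min, lat_min, lon_max, lat_max) -> "LocalProjection":
        return cls((lon_min + lon_max) / 2.0, (lat_min + lat_max) / 2.0)

    def to_xy(self, lon, lat):
        """lon/lat degrees → planar metres."""
        k = EARTH_RADIUS_KM * 1000.0
        x = np.radians(np.asarray(lon, dtype=float) - self.lon0) * k * math.cos(math.radians(self.lat0))
        y = np.radians(np.asarray(lat, dtype=float) - self.lat0) * k
        return x, y

    def to_lonlat(self, x, y):
        k = EARTH_RADIUS_KM * 1000.0
        lon = self.lon0 + np.degrees(np.asarray(x, dtype=float) / (k * math.cos(math.radians(self.lat0))))
        lat = self.lat0 + np.degrees(np.asarray(y, dtype=float) / k)
        return lon, lat

    def project_polygon(self, poly: Polygon) -> Polygon:
        def ring(coords):
            lon, lat = zip(*[(c[0], c[1]) for c in coords])
            x, y = self.to_xy(np.array(lon), np.array(lat))
            return list(zip(x, y))

        return Polygon(ring(poly.exterior.coords),
                       [ring(r.coords) for r in poly.interiors])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Neighborhood:
    """One tessellation cell: the analysis node."""

    id: str
    name: str
    municipality: str
    polygon: Polygon
    area_km2: float
    centroid: tuple[float, float]  # (lon, lat)


class NeighborhoodMap:
    """Immutable collection of neighborhoods with spatial indexing.

    Neighborhood ids are ``"municipality::name"`` so duplicate colonia
    names in different municipalities stay distinct.
    """

    def __init__(self, neighborhoods: Sequence[Neighborhood]):
        if not neighborhoods:
            raise ValueError("NeighborhoodMap requires at least one neighborhood")
        ids = [n.id for n in neighborhoods]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate neighborhood ids: {dup[:5]}")
        for n in neighborhoods:
            if not n.polygon.is_valid:
                raise GeometryError(f"invalid polygon for neighborhood {n.id!r}")
            if not n.area_km2 > 0:
                raise GeometryError(f"non-positive area for neighborhood {n.id!r}")
        self._list = list(neighborhoods)
        self._by_id = {n.id: n for n in self._list}
        self._tree = STRtree([n.polygon for n in self._list])

    def __len__(self) -> int:
        return len(self._list)

    def __iter__(self):
        return iter(self._list)

    def __contains__(self, nid: str) -> bool:
        return nid in self._by_id

    def __getitem__(self, nid: str) -> Neighborhood:
        return self._by_id[nid]

    @property
    def ids(self) -> list[str]:
        return [n.id for n in self._list]

    @property
    def municipalities(self) -> list[str]:
        return sorted({n.municipality for n in self._list})

    def municipality_of(self, nid: str) -> str:
        return self._by_id[nid].municipality

    def centroids(self) -> pd.DataFrame:
        """lon/lat centroids indexed by neighborhood id."""
        return pd.DataFrame(
            {"lon": [n.centroid[0] for n in self._list],
             "lat": [n.centroid[1] for n in self._list]},
            index=pd.Index(self.ids, name="neighborhood_id"),
        )

    def areas_km2(self) -> pd.Series:
        return pd.Series([n.area_km2 for n in self._list],
                         index=pd.Index(self.ids, name="neighborhood_id"),
                         name="area_km2")

    def bounds(self) -> tuple[float, float, float, float]:
        bs = np.array([n.polygon.bounds for n in self._list])
        return (bs[:, 0].min(), bs[:, 1].min(), bs[:, 2].max(), bs[:, 3].max())

    def projection(self) -> LocalProjection:
        return LocalProjection.for_bounds(*self.bounds())

    # -- construction -------------------------------------------------------

    @classmethod
    def from_polygons(cls, records: Iterable[tuple[str, str, Polygon]]) -> "NeighborhoodMap":
        """Build from ``(name, municipality, polygon)`` triples.

        Areas and centroids are computed in a local projection centred on
        the combined bounding box.
        """
        recs = list(records)
        if not recs:
            raise ValueError("no polygons given")
        allb = np.array([p.bounds for _, _, p in recs])
        proj = LocalProjection.for_bounds(allb[:, 0].min(), allb[:, 1].min(),
                                          allb[:, 2].max(), allb[:, 3].max())
        out = []
        for name, mun, poly in recs:
            nid = f"{mun}::{name}"
            planar = proj.project_polygon(poly)
            area_km2 = planar.area / 1e6
            cx, cy = planar.centroid.x, planar.centroid.y
            clon, clat = proj.to_lonlat(cx, cy)
            out.append(Neighborhood(nid, name, mun, poly, area_km2,
                                    (float(clon), float(clat))))
        return cls(out)

    # -- GeoJSON ------------------------------------------------------------

    @classmethod
    def from_geojson(cls, path) -> "NeighborhoodMap":
        """Read a FeatureCollection of polygons with ``name`` and
        ``municipality`` properties (the attribute schema shapefile-derived
        neighborhood layers carry)."""
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
        recs = []
        for i, feat in enumerate(gj.get("features", [])):
            props = feat.get("properties") or {}
            try:
                name = props["name"]
                mun = props["municipality"]
            except KeyError as e:
                raise FormatError(f"{path}: feature {i} missing property {e}") from None
            geom = shape(feat["geometry"])
            if geom.geom_type == "MultiPolygon":
                # keep the largest part; colonia multipolygons are slivers
                geom = max(geom.geoms, key=lambda g: g.area)
            if geom.geom_type != "Polygon":
                raise FormatError(f"{path}: feature {i} is {geom.geom_type}, not Polygon")
            recs.append((name, mun, geom))
        return cls.from_polygons(recs)

    def to_geojson(self, path) -> None:
        feats = [
            {"type": "Feature",
             "properties": {"name": n.name, "municipality": n.municipality},
             "geometry": mapping(n.polygon)}
            for n in self._list
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    # -- spatial queries ----------------------------------------------------

    def assign_points(self, lon: np.ndarray, lat: np.ndarray) -> list[str | None]:
        """Neighborhood id containing each point, or None if outside all.

        Boundary points go to the lexicographically smallest id among the
        polygons covering the point (deterministic tie-break).
        """
        pts = [Point(x, y) for x, y in zip(np.asarray(lon, float), np.asarray(lat, float))]
        assigned: list[str | None] = [None] * len(pts)
        if not pts:
            return assigned
        pi, gi = self._tree.query(pts, predicate="covered_by")
        for p, g in zip(pi, gi):
            nid = self._list[g].id
            if assigned[p] is None or nid < assigned[p]:
                assigned[p] = nid
        return assigned


class MunicipalityTable:
    """Municipality name → population (persons)."""

    def __init__(self, populations: Mapping[str, float]):
        for m, p in populations.items():
            if not p > 0:
                raise ValueError(f"non-positive population for {m!r}: {p}")
        self._pops = dict(populations)

    def __getitem__(self, municipality: str) -> float:
        return self._pops[municipality]

    def __contains__(self, municipality: str) -> bool:
        return municipality in self._pops

    def __len__(self) -> int:
        return len(self._pops)

    def items(self):
        return self._pops.items()

    def require(self, municipalities: Iterable[str]) -> None:
        missing = sorted(set(municipalities) - set(self._pops))
        if missing:
            raise KeyError(f"missing population for municipalities: {missing}")

    @classmethod
    def from_csv(cls, path) -> "MunicipalityTable":
        df = pd.read_csv(path)
        if not {"municipality", "population"} <= set(df.columns):
            raise FormatError(f"{path}: need columns municipality, population")
        return cls(dict(zip(df["municipality"], df["population"].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame(sorted(self._pops.items()),
                     columns=["municipality", "population"]).to_csv(path, index=False)


@dataclass
class HighwaySet:
    """Highway polylines: ordered lon/lat vertex lists with optional way ids."""

    polylines: list[list[tuple[float, float]]]
    way_ids: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        for i, line in enumerate(self.polylines):
            if len(line) < 2:
                raise GeometryError(f"polyline {i} has fewer than 2 vertices")
        if not self.way_ids:
            self.way_ids = [None] * len(self.polylines)

    def __len__(self) -> int:
        return len(self.polylines)

    def bounds(self) -> tuple[float, float, float, float]:
        pts = np.concatenate([np.asarray(l, float) for l in self.polylines])
        return (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())

    @classmethod
    def from_geojson(cls, path) -> "HighwaySet":
        with open(path) as fh:
            gj = json.load(fh)
        lines, ids = [], []

        def add(geom, wid):
            if geom["type"] == "LineString":
                lines.append([tuple(c[:2]) for c in geom["coordinates"]])
                ids.append(wid)
            elif geom["type"] == "MultiLineString":
                for part in geom["coordinates"]:
                    lines.append([tuple(c[:2]) for c in part])
                    ids.append(wid)
            else:
                raise FormatError(f"{path}: unsupported geometry {geom['type']}")

        if gj.get("type") == "FeatureCollection":
            for feat in gj["features"]:
                props = feat.get("properties") or {}
                add(feat["geometry"], props.get("way_id"))
        elif gj.get("type") in ("LineString", "MultiLineString"):
            add(gj, None)
        else:
            raise FormatError(f"{path}: expected LineString features")
        return cls(lines, ids)

    def to_geojson(self, path) -> None:
        feats = [
            {"type": "Feature",
             "properties": {"way_id": wid},
             "geometry": {"type": "LineString", "coordinates": [list(c) for c in line]}}
            for line, wid in zip(self.polylines, self.way_ids)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_osm_xml(cls, path,
                     highway_tags: Sequence[str] = ("motorway", "trunk", "primary"),
                     bbox: tuple[float, float, float, float] | None = DEFAULT_BBOX,
                     ) -> "HighwaySet":
        """Parse a (small) OSM XML export: nodes + ways tagged ``highway``.

        Only ways whose ``highway`` tag value is in *highway_tags* are kept
        ("high-speed roads"), and only nodes inside *bbox* (pass None to
        disable the filter).  Ways referencing missing nodes keep the
        resolvable vertices.
        """
        tree = ET.parse(path)
        root = tree.getroot()
        nodes: dict[str, tuple[float, float]] = {}
        for nd in root.iter("node"):
            lon, lat = float(nd.get("lon")), float(nd.get("lat"))
            if bbox is None or (bbox[0] <= lon <= bbox[2] and bbox[1] <= lat <= bbox[3]):
                nodes[nd.get("id")] = (lon, lat)
        lines, ids = [], []
        for way in root.iter("way"):
            tags = {t.get("k"): t.get("v") for t in way.findall("tag")}
            if tags.get("highway") not in highway_tags:
                continue
            coords = [nodes[ref.get("ref")] for ref in way.findall("nd")
                      if ref.get("ref") in nodes]
            if len(coords) >= 2:
                lines.append(coords)
                ids.append(way.get("id"))
        return cls(lines, ids)


# ---------------------------------------------------------------------------
# event table I/O
# ---------------------------------------------------------------------------

def read_events(path) -> pd.DataFrame:
    """Read an event CSV (``date, lat, lon, casualties`` [, title, url]).

    Malformed rows (unparseable date or coordinate, casualties < 1) are
    dropped, and a row-numbered report is attached as
    ``df.attrs["rejected"]`` (list of ``(row_number, reason)``, 1-based
    data rows).  A missing required column raises :class:`FormatError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rejected: list[tuple[int, str]] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        rec = dict(zip(raw.columns, row))
        try:
            date = pd.Timestamp(rec["date"])
            if pd.isna(date):
                raise ValueError("empty date")
            lat = float(rec["lat"])
            lon = float(rec["lon"])
            cas = int(float(rec["casualties"]))
            if cas < 1:
                raise ValueError("casualties < 1")
        except (ValueError, TypeError) as e:
            rejected.append((i, str(e) or type(e).__name__))
            continue
        rows.append({"date": date.normalize(), "lat": lat, "lon": lon,
                     "casualties": cas,
                     "title": rec.get("title", ""), "url": rec.get("url", "")})
    df = pd.DataFrame(rows, columns=["date", "lat", "lon", "casualties", "title", "url"])
    if len(df):
        df["date"] = pd.to_datetime(df["date"])
    df.attrs["rejected"] = rejected
    return df


def write_events(events: pd.DataFrame, path) -> None:
    """Write events as CSV with ISO-8601 dates in the source column order."""
    out = events.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = ["date", "lat", "lon", "casualties", "title", "url"]
    for c in cols:
        if c not in out.columns:
            out[c] = ""
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event → neighborhood assignment
# ---------------------------------------------------------------------------

def map_events(events: pd.DataFrame, nmap: NeighborhoodMap) -> tuple[pd.DataFrame, int]:
    """Assign each event to the neighborhood containing it.

    Events outside every polygon are dropped (the urban-area filter).
    Returns ``(mapped_events, n_dropped)``; row order is preserved and the
    operation is idempotent — any pre-existing ``neighborhood_id`` column
    is recomputed from coordinates.
    """
    if nmap is None or len(nmap) == 0:
        raise ValueError("empty NeighborhoodMap")
    if events.empty:
        out = events.copy()
        out["neighborhood_id"] = pd.Series(dtype=object)
        return out, 0
    assigned = nmap.assign_points(events["lon"].to_numpy(), events["lat"].to_numpy())
    out = events.copy()
    out["neighborhood_id"] = assigned
    kept = out[out["neighborhood_id"].notna()]
    return kept.reset_index(drop=True), int(len(out) - len(kept))


# ---------------------------------------------------------------------------
# contiguity and distances
# ---------------------------------------------------------------------------

def adjacency(nmap: NeighborhoodMap, mode: str = "queen") -> set[tuple[str, str]]:
    """Unordered pairs of contiguous neighborhoods.

    ``queen``: boundaries share at least one point.  ``rook``: boundaries
    share a segment of positive length (corner touches excluded).
    """
    if mode not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity mode {mode!r}")
    geoms = [n.polygon for n in nmap]
    ids = nmap.ids
    for nid, g in zip(ids, geoms):
        if not g.is_valid:
            raise GeometryError(f"invalid polygon for neighborhood {nid!r}")
    tree = STRtree(geoms)
    ai, bi = tree.query(geoms, predicate="intersects")
    pairs: set[tuple[str, str]] = set()
    for a, b in zip(ai, bi):
        if a >= b:
            continue
        inter = geoms[a].boundary.intersection(geoms[b].boundary)
        if inter.is_empty:
            continue
        if mode == "rook" and inter.length == 0:
            continue
        pairs.add(tuple(sorted((ids[a], ids[b]))))
    return pairs


def centroid_distance_km(a: Neighborhood, b: Neighborhood) -> float:
    """Great-circle distance between two neighborhood centroids."""
    return float(haversine_km(a.centroid[0], a.centroid[1],
                              b.centroid[0], b.centroid[1]))


def pairwise_centroid_distances(nmap: NeighborhoodMap) -> tuple[list[tuple[str, str]], np.ndarray]:
    """All unordered id pairs and their centroid haversine distances (km)."""
    cents = nmap.centroids()
    ids = list(cents.index)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    lon = cents["lon"].to_numpy()
    lat = cents["lat"].to_numpy()
    d = haversine_km(lon[iu], lat[iu], lon[ju], lat[ju])
    pairs = [(ids[i], ids[j]) for i, j in zip(iu, ju)]
    return pairs, np.asarray(d, dtype=float)
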