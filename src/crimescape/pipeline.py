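"""End-to-end orchestration: one config in, a directory of artifacts out.

Stage order: load/generate → map events → weekly series → PCC + permutation
null → spatial correlation curve per year → co-occurrence network per year
→ whole-period crime network + component table → highway p99.  Every stage
writes its CSV/GraphML product and records row counts in a JSON manifest;
identical config + seed gives byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import geoio, highways as hwy, networks, spatial, synth, weekly
from .errors import ConfigError, DegenerateStatisticError, StageError

log = logging.getLogger("crimescape")


@dataclass
class RunConfig:
    """Pipeline configuration: synthetic city OR real input paths.

    Exactly one of ``synthetic`` / the four input paths must be supplied.
    Switch flags default to the package's canonical analysis choices.
    """

    synthetic: synth.CityConfig | None = None
    events_path: str | None = None
    neighborhoods_path: str | None = None
    populations_path: str | None = None
    highways_path: str | None = None
    window: tuple | None = None
    n_iter: int = 1000
    seed: int = 0
    outdir: str = "crimescape_out"
    contiguity: str = "queen"
    proxy_mode: str = "literal"
    percentile_method: str = "linear"
    distance_geometry: str = "planar"
    cooc_adjacency_only: bool = False
    value: str = "casualties"

    def __post_init__(self):
        real = [self.events_path, self.neighborhoods_path,
                self.populations_path, self.highways_path]
        if self.synthetic is not None and any(p is not None for p in real):
            raise ConfigError("give either a synthetic config or real paths, not both")
        if self.synthetic is None and any(p is None for p in real):
            raise ConfigError("real-data runs need all four input paths")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None and isinstance(d["synthetic"], dict):
            sd = dict(d["synthetic"])
            if "planted_pairs" in sd:
                sd["planted_pairs"] = [tuple(p) for p in sd["planted_pairs"]]
            if "start_date" in sd and isinstance(sd["start_date"], str):
                sd["start_date"] = pd.Timestamp(sd["start_date"]).date()
            d["synthetic"] = synth.CityConfig(**sd)
        if d.get("window") is not None:
            d["window"] = tuple(d["window"])
        return cls(**d)

    def digest(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default,
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed,
                      "stages": {}, "outputs": [], "warnings": []}

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                try:
                    r = fn(*a, **kw)
                except DegenerateStatisticError as e:
                    manifest["warnings"].append(f"{name}: skipped ({e})")
                    log.warning("stage %s skipped: %s", name, e)
                    return None
                except Exception as e:
                    manifest["stages"][name] = {"status": "failed"}
                    _write_manifest(manifest, out)
                    raise StageError(name, e) from e
                manifest["stages"].setdefault(name, {})["status"] = "ok"
                return r
            return wrapped
        return deco

    def emit(path: Path):
        manifest["outputs"].append(str(path.relative_to(out)))

    # ---- load or generate --------------------------------------------------
    @stage("load")
    def _load():
        if config.synthetic is not None:
            city = synth.generate_city(config.synthetic)
            events = synth.generate_events(city, config.synthetic)
            nmap, pops, hw = city
            nmap.to_geojson(out / "neighborhoods.geojson")
            pops.to_csv(out / "populations.csv")
            hw.to_geojson(out / "highways.geojson")
            geoio.write_events(events, out / "events.csv")
            for f in ("neighborhoods.geojson", "populations.csv",
                      "highways.geojson", "events.csv"):
                emit(out / f)
        else:
            nmap = geoio.NeighborhoodMap.from_geojson(config.neighborhoods_path)
            pops = geoio.MunicipalityTable.from_csv(config.populations_path)
            p = str(config.highways_path)
            hw = (geoio.HighwaySet.from_osm_xml(p) if p.endswith((".osm", ".xml"))
                  else geoio.HighwaySet.from_geojson(p))
            events = geoio.read_events(config.events_path)
        return nmap, pops, hw, events

    nmap, pops, hw, events = _load()
    manifest["stages"]["load"].update(
        n_neighborhoods=len(nmap), n_events_in=len(events),
        n_highway_polylines=len(hw))
    if len(events) == 0:
        manifest["warnings"].append("load: zero events generated/read")
        log.warning("zero events in input")

    # ---- map ---------------------------------------------------------------
    @stage("map")
    def _map():
        return geoio.map_events(events, nmap)

    mapped, dropped = _map()
    manifest["stages"]["map"].update(n_mapped=len(mapped), n_dropped=dropped)
    assert len(mapped) + dropped == len(events)
    geoio.write_events(
        mapped.assign(title=mapped.get("title", ""), url=mapped.get("url", "")),
        out / "events_mapped.csv")
    emit(out / "events_mapped.csv")

    window = config.window
    if window is None and len(mapped):
        window = (mapped["date"].min(), mapped["date"].max())

    # ---- weekly + correlation ---------------------------------------------
    @stage("weekly")
    def _weekly():
        if not len(mapped):
            return None
        return weekly.weekly_aggregate(mapped, nmap, window=window,
                                       value=config.value)

    wmat = _weekly()
    if wmat is not None:
        manifest["stages"]["weekly"].update(
            n_weeks=wmat.n_weeks, n_municipalities=len(wmat.municipalities))

        @stage("correlate")
        def _corr():
            if len(wmat.municipalities) < 2 or wmat.n_weeks < 2:
                manifest["warnings"].append("correlate: too few municipalities/weeks")
                return None
            table = weekly.null_zscores(wmat, n_iter=config.n_iter,
                                        seed=config.seed)
            weekly.write_correlation_table(table, out / "municipal_correlation.csv")
            sq = weekly.correlation_square(table, wmat.municipalities)
            sq.to_csv(out / "municipal_correlation_matrix.csv")
            emit(out / "municipal_correlation.csv")
            emit(out / "municipal_correlation_matrix.csv")
            return table

        corr = _corr()
        if corr is not None:
            manifest["stages"]["correlate"].update(
                n_pairs=len(corr), n_significant=int(corr["significant"].sum()))

    # ---- yearly stages -----------------------------------------------------
    years = (sorted(pd.to_datetime(mapped["date"]).dt.year.unique().tolist())
             if len(mapped) else [])

    @stage("spatial")
    def _spatial():
        curves = []
        for year in years:
            try:
                curves.append(spatial.spatial_curve(
                    mapped, nmap, pops, year, proxy_mode=config.proxy_mode))
            except DegenerateStatisticError as e:
                manifest["warnings"].append(f"spatial[{year}]: skipped ({e})")
        if not curves:
            return None
        df = pd.concat(curves, ignore_index=True)
        df.to_csv(out / "spatial_correlation.csv", index=False)
        emit(out / "spatial_correlation.csv")
        return df

    curve = _spatial()
    manifest["stages"]["spatial"].update(
        n_rows=0 if curve is None else len(curve))

    @stage("adjacency")
    def _adj():
        return geoio.adjacency(nmap, mode=config.contiguity)

    adj = _adj()
    manifest["stages"]["adjacency"].update(n_pairs=len(adj))

    @stage("networks")
    def _nets():
        n_edges = 0
        for year in years:
            g = networks.cooccurrence_network(
                mapped, year, adjacency_pairs=adj if config.cooc_adjacency_only else None)
            networks.write_graphml(g, nmap, out / f"cooccurrence_{year}.graphml",
                                   events=mapped)
            networks.write_edgelist(g, out / f"cooccurrence_{year}.csv")
            emit(out / f"cooccurrence_{year}.graphml")
            emit(out / f"cooccurrence_{year}.csv")
            n_edges += g.number_of_edges()
        return n_edges

    manifest["stages"].setdefault("networks", {})
    manifest["stages"]["networks"].update(n_cooccurrence_edges=_nets() or 0)

    @stage("crime_network")
    def _crime():
        g = networks.crime_network(mapped, nmap, adj, window=window)
        networks.write_graphml(g, nmap, out / "crime_network.graphml",
                               events=mapped)
        comp = networks.component_table(g, nmap)
        comp.to_csv(out / "crime_components.csv", index=False)
        emit(out / "crime_network.graphml")
        emit(out / "crime_components.csv")
        return g, comp

    g, comp = _crime()
    manifest["stages"]["crime_network"].update(
        n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(),
        n_components=len(comp), n_main=int(comp["main_component"].sum()) if len(comp) else 0)

    @stage("highways")
    def _hwy():
        if not len(mapped) or len(hw) == 0:
            manifest["warnings"].append("highways: no events or highways, skipped")
            return None
        summary = hwy.p99_by_year(mapped, hw, method=config.percentile_method,
                                  geometry=config.distance_geometry)
        summary.to_csv(out / "highway_p99.csv", index=False)
        emit(out / "highway_p99.csv")
        return summary

    summary = _hwy()
    manifest["stages"]["highways"].update(
        n_years=0 if summary is None else len(summary))

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
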