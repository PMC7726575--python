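"""Co-occurrence and contiguity event networks.

Two constructions over the neighborhood tessellation:

* **Yearly co-occurrence network** — nodes are neighborhoods with at least
  one event in the year; two nodes are linked with weight = the number of
  distinct weeks in which *both* recorded at least one event
  (presence-based: a week with 3 events in one and 2 in the other still
  contributes +1).  Edge weights are classed grey (1–2), blue (3–7) and
  red (≥8).  Co-occurrence deliberately ignores polygon adjacency — the
  construction captures temporal, not spatial, coupling; an
  ``adjacency_only`` variant restricts edges to contiguous pairs.

* **Whole-period contiguity crime network** — nodes are neighborhoods with
  at least one event in the window; edges join pairs that are adjacent
  polygons.  Its connected components ("crime sectors") are summarised by
  size, edge count and the modal ("main") municipality; components with
  more than 10 edges are flagged as main components.

Weeks are the same Monday-anchored bins used by the weekly municipal
series; a year's network uses the weeks whose Monday falls in that
calendar year.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .geoio import NeighborhoodMap
from .weekly import monday_on_or_before

WEIGHT_CLASSES = ((1, 2, "grey"), (3, 7, "blue"), (8, None, "red"))


def weight_class(weight: int) -> str:
    """Fig-style co-occurrence weight class: 1–2 grey, 3–7 blue, ≥8 red."""
    if weight < 1:
        raise ValueError("co-occurrence weight must be >= 1")
    for lo, hi, label in WEIGHT_CLASSES:
        if weight >= lo and (hi is None or weight <= hi):
            return label
    raise AssertionError("unreachable")


def _week_monday(dates) -> pd.Series:
    d = pd.to_datetime(pd.Series(dates)).dt.normalize()
    return d - pd.to_timedelta(d.dt.weekday, unit="D")


def cooccurrence_network(events: pd.DataFrame, year: int,
                         adjacency_pairs: set | None = None) -> nx.Graph:
    """Same-week co-occurrence network for one calendar year.

    Isolated violent neighborhoods are kept as degree-0 nodes.  Passing
    *adjacency_pairs* restricts edges to contiguous neighborhood pairs
    (the combined spatial+temporal variant).
    """
    if "neighborhood_id" not in events.columns:
        raise ValueError("events must be mapped to neighborhoods first")
    if events.empty:
        raise ValueError("no events: year outside the data window")
    dmin, dmax = events["date"].min(), events["date"].max()
    if not (dmin.year <= year <= dmax.year):
        raise ValueError(f"year {year} outside data window "
                         f"[{dmin.year}, {dmax.year}]")
    monday = _week_monday(events["date"])
    sel = events[monday.dt.year.to_numpy() == year]
    g = nx.Graph(year=year)
    if sel.empty:
        return g
    sel = sel.assign(week_monday=_week_monday(sel["date"]).to_numpy())
    active = sel.groupby("week_monday")["neighborhood_id"].agg(lambda s: sorted(set(s)))
    g.add_nodes_from(sorted(set(sel["neighborhood_id"])))
    for nbhds in active:
        for a, b in combinations(nbhds, 2):
            if adjacency_pairs is not None and (a, b) not in adjacency_pairs:
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    for a, b, data in g.edges(data=True):
        data["weight_class"] = weight_class(data["weight"])
    return g


def crime_network(events: pd.DataFrame, nmap: NeighborhoodMap,
                  adjacency_pairs: set,
                  window: tuple | None = None) -> nx.Graph:
    """Whole-period network of adjacent violent neighborhoods.

    Nodes: neighborhoods with ≥1 event in *window* (default: all events).
    Edges: pairs that are both violent and adjacent polygons.  Node
    attributes carry municipality and event count.
    """
    if "neighborhood_id" not in events.columns:
        raise ValueError("events must be mapped to neighborhoods first")
    ev = events
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        ev = ev[(ev["date"] >= start) & (ev["date"] <= end)]
    counts = ev.groupby("neighborhood_id").size()
    violent = set(counts.index)
    g = nx.Graph()
    for nid in sorted(violent):
        g.add_node(nid, municipality=nmap.municipality_of(nid),
                   n_events=int(counts[nid]))
    for a, b in adjacency_pairs:
        if a in violent and b in violent:
            g.add_edge(a, b)
    return g


def component_composition(nodes, nmap: NeighborhoodMap) -> tuple[str, int, float, bool]:
    """Modal municipality of a component: (name, count, proportion, tied).

    Ties are broken lexicographically and flagged.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty component")
    tally = pd.Series([nmap.municipality_of(n) for n in nodes]).value_counts()
    top = int(tally.max())
    winners = sorted(tally.index[tally == top])
    return winners[0], top, top / len(nodes), len(winners) > 1


def component_table(g: nx.Graph, nmap: NeighborhoodMap,
                    main_edge_threshold: int = 10) -> pd.DataFrame:
    """Per-component composition summary, largest first.

    ``main_component`` is True when the component has strictly more than
    *main_edge_threshold* edges.
    """
    rows = []
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    for idx, comp in enumerate(comps, start=1):
        sub = g.subgraph(comp)
        main_mun, count, prop, tied = component_composition(comp, nmap)
        rows.append({"component": idx,
                     "n_neighborhoods": len(comp),
                     "n_edges": sub.number_of_edges(),
                     "main_municipality": main_mun,
                     "count_in_main": count,
                     "proportion": prop,
                     "municipality_tie": tied,
                     "main_component": sub.number_of_edges() > main_edge_threshold})
    return pd.DataFrame(rows, columns=["component", "n_neighborhoods", "n_edges",
                                       "main_municipality", "count_in_main",
                                       "proportion", "municipality_tie",
                                       "main_component"])


def write_graphml(g: nx.Graph, nmap: NeighborhoodMap, path,
                  events: pd.DataFrame | None = None) -> None:
    """GraphML export with municipality / event-count node attributes."""
    out = g.copy()
    counts = (events.groupby("neighborhood_id").size()
              if events is not None and len(events) else pd.Series(dtype=int))
    for nid, data in out.nodes(data=True):
        data.setdefault("municipality", nmap.municipality_of(nid))
        data.setdefault("n_events", int(counts.get(nid, 0)))
    nx.write_graphml(out, path)


def write_edgelist(g: nx.Graph, path) -> None:
    rows = [{"neighborhood_1": a, "neighborhood_2": b,
             "weight": d.get("weight", 1),
             "weight_class": d.get("weight_class", "")}
            for a, b, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["neighborhood_1", "neighborhood_2",
                                "weight", "weight_class"]).to_csv(path, index=False)
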