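"""Co-occurrence networks, weight classes, contiguity crime networks."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import crimescape as cs

from conftest import SEED, make_events


class TestWeightClass:
    @pytest.mark.parametrize("w,label", [
        (1, "grey"), (2, "grey"), (3, "blue"), (5, "blue"), (7, "blue"),
        (8, "red"), (12, "red"), (40, "red"),
    ])
    def test_class_bands(self, w, label):
        assert cs.weight_class(w) == label

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            cs.weight_class(0)


class TestCooccurrenceNetwork:
    def test_single_event_gives_one_isolated_node(self, grid10):
        _, nmap, _, _ = grid10
        ev = make_events([("2011-03-05", nmap.ids[3])])
        g = cs.cooccurrence_network(ev, 2011)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_two_shared_weeks_weight_two(self, grid10):
        _, nmap, _, _ = grid10
        a, b = nmap.ids[0], nmap.ids[5]
        # weeks of 2011-01-17 (wk 3 of Jan) and 2011-02-28; different days
        ev = make_events([("2011-01-17", a), ("2011-01-19", b),
                          ("2011-02-28", a), ("2011-03-06", b)])
        g = cs.cooccurrence_network(ev, 2011)
        assert g[a][b]["weight"] == 2
        assert g[a][b]["weight_class"] == "grey"

    def test_planted_pairs_recovered_exactly(self):
        cfg = cs.CityConfig(base_rate=0.0,
                            planted_pairs=[(2, 30, 5), (2, 77, 2)], seed=SEED)
        city = cs.generate_city(cfg)
        ev = cs.generate_events(city, cfg)
        mapped, _ = cs.map_events(ev, city[0])
        g = cs.cooccurrence_network(mapped, 2011)
        a = cs.cell_id(cfg, 2)
        b = cs.cell_id(cfg, 30)
        c = cs.cell_id(cfg, 77)
        assert set(map(frozenset, g.edges())) == {frozenset((a, b)),
                                                  frozenset((a, c))}
        assert g[a][b]["weight"] == 5 and g[a][b]["weight_class"] == "blue"
        assert g[a][c]["weight"] == 2 and g[a][c]["weight_class"] == "grey"

    def test_weights_match_week_set_intersection_oracle(self, busy_city):
        _, (nmap, _, _), mapped, _ = busy_city
        g = cs.cooccurrence_network(mapped, 2011)
        monday = (pd.to_datetime(mapped["date"]).dt.normalize()
                  - pd.to_timedelta(pd.to_datetime(mapped["date"]).dt.weekday,
                                    unit="D"))
        in_year = mapped[monday.dt.year == 2011]
        weeks_of = in_year.groupby("neighborhood_id").apply(
            lambda s: set(monday.loc[s.index]), include_groups=False)
        for a, b in combinations(sorted(weeks_of.index), 2):
            shared = len(weeks_of[a] & weeks_of[b])
            got = g[a][b]["weight"] if g.has_edge(a, b) else 0
            assert got == shared, (a, b)

    def test_presence_based_not_event_product(self, grid10):
        _, nmap, _, _ = grid10
        a, b = nmap.ids[0], nmap.ids[1]
        # 3 events in a and 2 in b within one week → weight 1, not 6
        ev = make_events([("2011-01-03", a), ("2011-01-04", a),
                          ("2011-01-05", a), ("2011-01-06", b),
                          ("2011-01-07", b)])
        g = cs.cooccurrence_network(ev, 2011)
        assert g[a][b]["weight"] == 1

    def test_year_outside_window_rejected(self, busy_city):
        _, _, mapped, _ = busy_city
        with pytest.raises(ValueError):
            cs.cooccurrence_network(mapped, 1990)

    def test_adjacency_restricted_variant(self, grid10):
        _, nmap, _, _ = grid10
        a, far = nmap.ids[0], nmap.ids[99]
        ev = make_events([("2011-01-03", a), ("2011-01-04", far)])
        adj = cs.adjacency(nmap)
        g = cs.cooccurrence_network(ev, 2011, adjacency_pairs=adj)
        assert g.number_of_edges() == 0  # distant pair suppressed
        g_free = cs.cooccurrence_network(ev, 2011)
        assert g_free.number_of_edges() == 1


class TestCrimeNetwork:
    def test_no_events_empty_network(self, grid10):
        _, nmap, _, _ = grid10
        ev = make_events([]).reindex(columns=["date", "lat", "lon", "casualties",
                                              "title", "url", "neighborhood_id"])
        adj = cs.adjacency(nmap)
        g = cs.crime_network(ev, nmap, adj)
        assert g.number_of_nodes() == 0

    def test_3x3_all_violent_single_component(self):
        cfg = cs.CityConfig(n_rows=3, n_cols=3, n_municipalities=1,
                            populations=[1e5], seed=SEED)
        nmap, _, _ = cs.generate_city(cfg)
        ev = make_events([("2011-01-05", nid) for nid in nmap.ids])
        g = cs.crime_network(ev, nmap, cs.adjacency(nmap))
        comps = list(nx.connected_components(g))
        assert len(comps) == 1 and len(comps[0]) == 9

    def test_event_free_middle_row_splits_5x5_into_two_tens(self):
        cfg = cs.CityConfig(n_rows=5, n_cols=5, n_municipalities=1,
                            populations=[1e5], seed=SEED)
        nmap, _, _ = cs.generate_city(cfg)
        violent = [cs.cell_id(cfg, k) for k in range(25) if not 10 <= k < 15]
        ev = make_events([("2011-01-05", nid) for nid in violent])
        g = cs.crime_network(ev, nmap, cs.adjacency(nmap))
        sizes = sorted(len(c) for c in nx.connected_components(g))
        assert sizes == [10, 10]

    def test_all_violent_equals_full_contiguity_graph(self, grid10):
        _, nmap, _, _ = grid10
        adj = cs.adjacency(nmap)
        ev = make_events([("2011-01-05", nid) for nid in nmap.ids])
        g = cs.crime_network(ev, nmap, adj)
        assert set(map(frozenset, g.edges())) == set(map(frozenset, adj))

    def test_every_edge_joins_adjacent_polygons(self, busy_city):
        _, (nmap, _, _), mapped, _ = busy_city
        adj = cs.adjacency(nmap)
        g = cs.crime_network(mapped, nmap, adj)
        for a, b in g.edges():
            assert tuple(sorted((a, b))) in adj

    def test_component_bookkeeping_sums(self, busy_city):
        _, (nmap, _, _), mapped, _ = busy_city
        g = cs.crime_network(mapped, nmap, cs.adjacency(nmap))
        t = cs.component_table(g, nmap)
        assert t["n_neighborhoods"].sum() == g.number_of_nodes()
        assert t["n_edges"].sum() == g.number_of_edges()

    def test_main_flag_strictly_above_10_edges(self):
        # a 1×11 strip path has exactly 10 edges; 1×12 has 11
        for n_cols, is_main in [(11, False), (12, True)]:
            cfg = cs.CityConfig(n_rows=1, n_cols=n_cols, n_municipalities=1,
                                populations=[1e5], seed=SEED)
            nmap, _, _ = cs.generate_city(cfg)
            ev = make_events([("2011-01-05", nid) for nid in nmap.ids])
            g = cs.crime_network(ev, nmap, cs.adjacency(nmap))
            t = cs.component_table(g, nmap)
            assert t["n_edges"].iloc[0] == n_cols - 1
            assert bool(t["main_component"].iloc[0]) is is_main


class TestComponentComposition:
    def _map_with_munis(self, munis):
        from shapely.geometry import box
        recs = []
        for k, m in enumerate(munis):
            recs.append((f"N{k}", m,
                         box(-100.3 + k * 0.01, 25.7, -100.295 + k * 0.01, 25.705)))
        return cs.NeighborhoodMap.from_polygons(recs)

    def test_homogeneous_component_proportion_one(self):
        nmap = self._map_with_munis(["X"] * 4)
        main, count, prop, tied = cs.component_composition(nmap.ids, nmap)
        assert (main, count, prop, tied) == ("X", 4, 1.0, False)

    def test_three_of_four(self):
        nmap = self._map_with_munis(["X", "X", "X", "Y"])
        main, count, prop, tied = cs.component_composition(nmap.ids, nmap)
        assert (main, count, prop) == ("X", 3, 0.75)

    def test_tie_breaks_lexicographically_and_flags(self):
        nmap = self._map_with_munis(["B", "B", "A", "A"])
        main, count, prop, tied = cs.component_composition(nmap.ids, nmap)
        assert main == "A" and tied

    def test_random_labels_match_brute_force_mode(self):
        rng = np.random.default_rng(SEED)
        labels = [f"M{v}" for v in rng.integers(0, 5, 50)]
        nmap = self._map_with_munis(labels)
        main, count, prop, _ = cs.component_composition(nmap.ids, nmap)
        from collections import Counter
        tally = Counter(labels)
        best = max(tally.values())
        assert count == best
        assert main == sorted(m for m, c in tally.items() if c == best)[0]
        assert prop == pytest.approx(best / 50)


def test_graphml_and_edgelist_export(tmp_path, busy_city):
    _, (nmap, _, _), mapped, _ = busy_city
    g = cs.cooccurrence_network(mapped, 2011)
    p = tmp_path / "g.graphml"
    cs.write_graphml(g, nmap, p, events=mapped)
    back = nx.read_graphml(p)
    assert back.number_of_nodes() == g.number_of_nodes()
    assert back.number_of_edges() == g.number_of_edges()
    some = next(iter(back.nodes(data=True)))[1]
    assert "municipality" in some and "n_events" in some
    csv = tmp_path / "g.csv"
    cs.write_edgelist(g, csv)
    df = pd.read_csv(csv)
    assert len(df) == g.number_of_edges()
    assert set(df["weight_class"]) <= {"grey", "blue", "red"}
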