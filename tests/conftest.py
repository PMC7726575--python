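import numpy as np
import pandas as pd
import pytest

import crimescape as cs

# package-wide test seed, fixed once
SEED = 0


@pytest.fixture(scope="session")
def grid10():
    """10×10 single-municipality city (no events)."""
    cfg = cs.CityConfig(n_rows=10, n_cols=10, n_municipalities=1,
                        populations=[1_000_000.0], base_rate=0.0, seed=SEED)
    nmap, pops, hw = cs.generate_city(cfg)
    return cfg, nmap, pops, hw


@pytest.fixture(scope="session")
def busy_city():
    """Mid-size city with hotspots and events, mapped, for reuse."""
    cfg = cs.CityConfig(n_rows=8, n_cols=8, n_municipalities=3,
                        populations=[400_000.0, 250_000.0, 150_000.0],
                        base_rate=0.08, hotspot_ids=[27, 28],
                        hotspot_multiplier=6.0, n_weeks=60, seed=SEED)
    city = cs.generate_city(cfg)
    events = cs.generate_events(city, cfg)
    mapped, dropped = cs.map_events(events, city[0])
    return cfg, city, mapped, dropped


def make_events(rows):
    """Hand-built mapped event table from (date, neighborhood_id[, casualties])."""
    recs = []
    for r in rows:
        date, nid = r[0], r[1]
        cas = r[2] if len(r) > 2 else 1
        recs.append({"date": pd.Timestamp(date), "lat": 25.7, "lon": -100.3,
                     "casualties": cas, "title": "", "url": "",
                     "neighborhood_id": nid})
    return pd.DataFrame(recs)


def weekly_matrix(values, anchor="2011-01-03"):
    """WeeklyCountMatrix straight from a municipality→vector dict."""
    df = pd.DataFrame({m: np.asarray(v, float) for m, v in values.items()}).T
    df.index.name = "municipality"
    df.columns = range(df.shape[1])
    weeks = pd.DatetimeIndex([pd.Timestamp(anchor) + pd.Timedelta(days=7 * i)
                              for i in range(df.shape[1])])
    return cs.WeeklyCountMatrix(df, weeks)
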