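"""Event-to-highway distances and the yearly 99th percentile.

Compares two cities that differ only in highway bias: in the biased one,
70% of events are relocated to within 500 m of the diagonal highway.  The
per-year p99 — the distance such that 99% of events lie at least as close
to a highway — shrinks accordingly.
"""

import numpy as np

import crimescape as cs

base = dict(n_rows=10, n_cols=10, n_municipalities=1, populations=[1_000_000],
            base_rate=0.15, n_weeks=104, seed=61, highway_halfwidth_km=0.5)

city = cs.generate_city(cs.CityConfig(**base))
for label, bias in [("unbiased", 0.0), ("biased 70%", 0.7)]:
    cfg = cs.CityConfig(**base, highway_bias=bias)
    events = cs.generate_events(city, cfg)
    summary = cs.p99_by_year(events, city[2])
    d = cs.min_distance_m(events, city[2])
    print(f"{label:11s} median {np.median(d):7.0f} m   "
          + "  ".join(f"p99[{int(r.year)}]={r.p99_m:6.0f} m"
                      for r in summary.itertuples()))
# The biased city's median collapses under 500 m; its p99 falls toward the
# upper quantiles of the unbiased distance distribution.
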