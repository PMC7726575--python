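# crimescape

Spatio-temporal analysis of geolocated violent-event data over an urban
neighborhood tessellation.

Given (a) a dated, geolocated casualty table, (b) a polygon layer of
neighborhoods grouped into municipalities, (c) municipal populations and
(d) highway polylines, the package runs the standard desk analyses of how
violence is organised in a metropolitan area:

- **event mapping** — assign each event to the neighborhood polygon that
  contains it (events outside every polygon are dropped as non-urban);
- **municipal correlation** — weekly Monday-anchored casualty series per
  municipality, all pairwise Pearson correlation coefficients (PCC), and a
  permutation-null significance test: each municipality's weeks are
  independently reshuffled 1000 times,
  `Z = (PCC_obs − mean_null) / sd_null`, pairs with `Z > 3` flagged;
- **spatial correlation** — the distance-binned statistic

  ```
  G(t, r) = Σ_{(i,j)∈N, i≠j} (h_i − μ)(h_j − μ) / (|N| σ²)
  ```

  over neighborhood pairs whose centroid distance falls in quantile bin
  `r` (20 bins at 0.05 quantile steps), where `h_k` is the per-capita
  count of neighborhood `k` with the population proxy `A_i · P_m`
  (neighborhood area × municipality population) and μ, σ² are the global
  mean and population variance of `h`;
- **co-occurrence networks** — per year, link two neighborhoods with
  weight equal to the number of distinct weeks in which both recorded at
  least one event (weight classes: grey 1–2, blue 3–7, red ≥ 8);
- **crime networks** — over the whole period, link *adjacent* (queen
  contiguity) violent neighborhoods; connected components are "crime
  sectors", components with more than 10 edges are main components, and
  each is summarised by its dominant municipality;
- **highway proximity** — per-event distance to the nearest highway
  polyline and the yearly 99th percentile (the distance such that 99% of
  events lie at least as close to a highway).

A first-class **synthetic city generator** emulates all four inputs — a
grid tessellation in WGS84 lon/lat split into contiguous municipalities,
per-neighborhood Poisson event rates with hotspot multipliers and a
temporal wave, planted same-week co-occurring pairs, and a highway with a
configurable fraction of events relocated near it — so every stage is
testable, with known ground truth, without any downloads.

## Worked example

`examples/` holds one short script per capability. For instance,
municipal correlation with a shared mid-window surge of violence
(`python examples/02_municipal_correlation.py`):

```
municipality_1 municipality_2    pcc  null_mean  null_sd      z  significant  undefined
           M00            M02 0.7224     0.0073   0.1092 6.5469         True        False
           M00            M01 0.7285    -0.0004   0.1148 6.3513         True        False
...
significant pairs (Z > 3): 6 of 6
```

Every pair's weekly series rides the same temporal wave, so the observed
PCC (~0.6–0.73) sits far above the reshuffled null (mean ≈ 0,
sd ≈ 0.11), giving Z-scores of 5–6.5: all six municipality pairs are
significantly synchronised.

The spatial-correlation example plants a hotspot block and prints the
G(t, r) curve — positive (≈ 0.5) in the shortest-distance bin, decaying
through zero and negative at long range — together with the exact
conservation check `Σ |N|·G = −n/2` that the binned values must satisfy.

Library use mirrors the scripts:

```python
import crimescape as cs

cfg = cs.CityConfig(n_rows=10, n_cols=10, n_municipalities=4,
                    populations=[4e5, 3e5, 2e5, 1e5],
                    base_rate=0.05, n_weeks=52, seed=11)
nmap, pops, highways = cs.generate_city(cfg)
events = cs.generate_events((nmap, pops, highways), cfg)
mapped, dropped = cs.map_events(events, nmap)
table = cs.null_zscores(cs.weekly_aggregate(mapped, nmap), seed=11)
```

A thin CLI wraps the same functions for shell pipelines
(`crimescape run-all --config cfg.json --seed 1 --outdir out/` plus
per-stage subcommands `synth`, `map`, `correlate`, `spatial`, `networks`,
`highways`); `run-all` writes every tabular/GraphML artifact and a JSON
manifest with the config hash, seed and per-stage row counts, and is
byte-reproducible for a fixed config and seed.

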