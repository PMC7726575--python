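# Methods

This note documents the models, conventions and design choices behind
`crimescape`, in the order the pipeline runs them.

## Data model

Events are rows of `(date, lat, lon, casualties)` in WGS84 degrees, with
`casualties ≥ 1`; pass-through `title`/`url` columns are preserved but
never used analytically. Neighborhoods are valid polygons with a name and
a municipality; the internal id is `"municipality::name"` so duplicate
neighborhood names in different municipalities stay distinct. All
analysis joins flow through `neighborhood_id` after point-in-polygon
assignment.

Metric geometry uses two conventions, chosen per operation:

- **Sphere** (haversine, `R = 6371.0088 km`) for centroid-to-centroid
  distances.
- **Local equirectangular projection** (`x = R·cosφ₀·λ`, `y = R·φ`,
  centred on the data bounding box) wherever planar geometry is needed:
  polygon areas, centroids, and point-to-segment distances. On a patch
  spanning under ~1.5° the projection error is orders of magnitude below
  the precision of any reported quantity; a spherical (cross-track)
  alternative for highway distances is switchable via
  `geometry="sphere"`, and on sub-degree segments the two agree to ~1 m.

Event-to-polygon assignment uses an STRtree with a `covered_by`
predicate, so boundary points are included; a point covered by several
polygons (a shared boundary) goes to the lexicographically smallest id —
an arbitrary but deterministic tie-break for a measure-zero case. Events
inside no polygon are dropped and counted, mirroring the urban-area
filter a real study applies.

Polygon contiguity defaults to **queen** (boundaries share at least one
point, including corner touches); `mode="rook"` requires a shared segment
of positive length. On grid tessellations both match index arithmetic
exactly, which the tests exploit.

## Weekly municipal correlation

Weeks are consecutive 7-day bins anchored at the **Monday on or before
the window start** (ISO-style alignment — a reproducible convention, since
weekly aggregation requires some anchor). Casualties (not event counts)
are summed per municipality per bin; a `value="events"` switch counts
events instead. Per-100k scaling is available but immaterial to the
correlation itself: the PCC is invariant under per-municipality affine
rescaling (tested).

Significance uses a permutation null: in each of `n_iter = 1000`
iterations every municipality's weekly vector is permuted independently,
all pairwise PCCs are recomputed, and each observed PCC is standardised
against its pair's null distribution (`sd` with ddof = 1; for the
two-municipality case a vectorised fast path computes all permutations at
once). Pairs involving a zero-variance series, or with zero null spread,
are reported as *undefined* — never coerced to 0 — and excluded from the
significance ranking. The `Z > 3` flag is one-sided by design (the rule
the analysis reports on).

**Limitation**: independent permutation destroys autocorrelation as well
as cross-correlation, so Z-scores are calibrated against an exchangeable
null, not an autocorrelation-preserving one. Block or rotation nulls are
a natural extension point but are deliberately out of scope. Under
independent inputs the Z-scores are close to standard normal (the
calibration run measures mean ≈ 0.007, sd ≈ 1.01, `P(|Z|>3)` ≈ 0.006 over
500 pairs of length-300 Poisson(2) series).

## Spatial correlation G(t, r)

For a calendar year *t* (configurable to any window):

    G(t, r) = Σ_{(i,j)∈N, i≠j} (h_i − μ)(h_j − μ) / (|N| σ²)

- `h_k = count_k / (A_k · P_m(k))` — per-capita counts through the
  area-times-municipal-population proxy, used because per-neighborhood
  populations are typically unavailable. The proxy is taken literally as
  the product (units km²·persons); an `area_fraction` mode
  (`(A_i/Σ_m A)·P_m`, true persons shared by area) is available for
  sensitivity analysis, and G is invariant to the difference whenever
  municipality areas are equal (any per-municipality rescaling of h that
  is globally affine leaves G unchanged).
- μ and σ² are **global** moments over all neighborhoods — including
  zero-event ones — with σ² the population (divide-by-n) variance. A
  `restrict_to_active` flag recomputes everything over event-bearing
  neighborhoods only.
- Pair distance is centroid-to-centroid haversine; bins are the 0, 0.05,
  …, 1.0 quantiles of the full pairwise-distance distribution (20
  half-open intervals `[lo, hi)`, the last closed). Degenerate distance
  distributions that collapse quantile edges raise an error rather than
  silently merging bins.
- Pairs are unordered and i ≠ j, each counted once.

These conventions make an exact identity available: since deviations sum
to zero, `Σ_bins |N_b|·G_b = −(1/2)·Σ_k (h_k−μ)²/σ² = −n/2`. The test
suite and the acceptance script verify it to 1e−10; it fails if the
moments are computed per-bin, the variance uses ddof = 1, or any pair is
double-counted — which is precisely why it is the right regression guard.
Zero-variance years (e.g. no events) raise a degenerate-statistic error;
the pipeline skips such years with a logged warning.

## Event networks

**Co-occurrence (per year)**: nodes are neighborhoods with ≥ 1 event in
the year; the weight of edge (a, b) is the number of *distinct weeks* in
which both were active — presence-based, so a week with 3 events in `a`
and 2 in `b` contributes +1, not +6. Weight classes: grey 1–2, blue 3–7,
red ≥ 8 (the red class is open-ended; observed maxima near 12 reflect
data, not a cap). Weeks are the same Monday-anchored bins as the
municipal series, and a year owns the weeks whose Monday falls in it —
calendar assignment, not ISO week-years; the difference only touches the
few days around New Year. Co-occurrence deliberately ignores adjacency —
it measures temporal coupling at any range; an `adjacency_pairs` argument
restricts edges to contiguous pairs for the combined spatial+temporal
variant.

**Crime network (whole period)**: nodes are violent neighborhoods, edges
join pairs that are *both* violent and adjacent polygons. Connected
components are the "crime sectors"; a component is a *main component*
when it has strictly more than 10 edges. Per-component composition
reports the modal municipality, its count and proportion; ties are broken
lexicographically and flagged.

Exports: GraphML (node attributes municipality and event count; edge
attributes weight and class) and edge-list/component CSVs.

## Highway proximity

Per event: the minimum over all highway polyline segments of the
point-to-segment distance (projected planar by default; degenerate
segments handled as points). Per year: the 99th percentile by **linear
interpolation between order statistics** (numpy's default), with a
nearest-rank option — beyond a few hundred events the two differ by less
than a metre. Single-event years report that distance. Which OSM way
types count as "highway" is a reader parameter, defaulting to
motorway/trunk/primary.

## Synthetic city generator

The generator defines the study conditions for all tests; it emulates the
statistical structure the analysis assumes, not urban realism.

- **Tessellation**: an `n_rows × n_cols` grid of rectangles of
  `cell_size_km` (default 1 km) side, placed in lon/lat near
  (−100.35, 25.65) so projection code paths run at a realistic latitude.
  A grid (rather than, say, a Voronoi tessellation) makes adjacency
  analytically known, so contiguity tests are exact. Municipalities are
  contiguous blocks obtained by splitting a boustrophedon (snake) walk of
  the cells into near-equal runs — every run is rook-connected by
  construction, for any grid shape and municipality count.
- **Events**: per-neighborhood, per-week Poisson counts with rate
  `base_rate · hotspot_multiplier(k) · wave(w)`. Default
  `base_rate = 0.05` events/neighborhood/week — for a ~100-neighborhood
  city over a year this yields a few hundred events, the same order as a
  metropolitan homicide record, with most neighborhoods silent and a
  minority active. Coordinates are uniform within the source polygon;
  dates are uniform within the week. The `wave` list is a
  piecewise-constant temporal multiplier (expanded to equal-width blocks,
  or applied element-wise when its length equals `n_weeks`).
- **Casualty marks** default to 1; a zero-truncated geometric hook
  exists because the mark distribution is plumbing, not a modelled
  quantity.
- **Planted co-occurrences**: each `(a, b, n_weeks)` entry forces ≥ 1
  event in both neighborhoods in `n_weeks` distinct weeks. Weeks are
  drawn without replacement *across* pairs while weeks remain, so
  different planted pairs never collide on a week and the downstream
  network recovers the planted weights exactly when `base_rate = 0`.
- **Highway bias**: each event is independently relocated with
  probability `highway_bias` to a point within `highway_halfwidth_km` of
  the highway (uniform along its length, uniform radial offset).
  Relocated points may leave the tessellation; the mapping stage then
  drops them, which is itself a tested code path.
- **Determinism**: one seed, with per-stage substreams spawned via
  `numpy` `SeedSequence`; identical config + seed gives identical output
  byte-for-byte through the whole pipeline.

What the generator does **not** emulate: street networks, demographic
covariates, spatially varying polygon shapes and sizes, reporting biases
of newspaper-derived records, or offender/victim structure. Passing tests
therefore demonstrate correctness of the statistical machinery under
known ground truth — not that real data satisfies the generator's
assumptions.

## Numerical and degenerate-input choices

- Undefined statistics (zero variance, zero null sd, empty pair sets)
  raise or flag; nothing is silently coerced to 0.
- The pipeline treats degenerate stages (zero events, too few
  municipalities) as warnings and continues, writing whatever artifacts
  remain well-defined, with the full account in the manifest.
- Week bins, quantile bin edges and percentile conventions are all
  documented defaults with explicit switches; every switch defaults to
  the choice the worked examples and acceptance runs use.
- Problem sizes in tests and the acceptance script (grids of 25–144
  cells, 500 calibration pairs × 1000 permutations, 1000-point
  point-in-polygon sweeps) were chosen as the smallest sizes at which the
  checked properties are sharp — oracle identities hold to 1e−10
  regardless of size, and the calibration bands are comfortably resolved
  at 500 pairs.

## Known limitations

- The permutation null is exchangeable (see above); heavy
  autocorrelation in real series would inflate Z-scores.
- The per-capita proxy has units km²·persons, not persons; G is
  insensitive to global rescalings but not to the proxy's *relative*
  weighting across municipalities of different area. Both proxy modes are
  exposed for exactly this reason.
- Centroid distance understates adjacency-scale proximity for elongated
  polygons; on near-square tessellations the effect is negligible.
- Reading binary ESRI shapefiles is out of scope; neighborhood layers
  are consumed as GeoJSON with the same attribute semantics (name,
  municipality), and highway data as GeoJSON LineStrings or plain OSM
  XML.
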