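"""Distance-binned spatial correlation of per-capita event counts.

For a time window *t* (a calendar year by default) and a set *N* of
neighborhood pairs whose centroid distance falls in interval *r*::

    G(t, r) = Σ_{(i,j)∈N, i≠j} (h_i − μ)(h_j − μ) / (|N| σ²)

where ``h_k`` is the per-capita count of neighborhood *k*, and μ, σ² are
the mean and *population* variance of h over all neighborhoods (global
moments, not per-bin).  Because neighborhood populations are typically
unavailable, the per-capita denominator is the proxy ``A_i · P_m`` — the
neighborhood's area times its municipality's population.  Distance bins
are the 0, 0.05, …, 1.0 quantiles of the pairwise centroid-distance
distribution (20 intervals).

With population-variance normalisation and global moments the binned
values satisfy an exact conservation identity::

    Σ_bins |N_b| · G_b = −(1/2) Σ_k (h_k − μ)² / σ²  = −n/2

since the deviations sum to zero; this is used as a correctness check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticError
from .geoio import MunicipalityTable, NeighborhoodMap, pairwise_centroid_distances


def percapita_proxy(nmap: NeighborhoodMap, pops: MunicipalityTable,
                    mode: str = "literal") -> pd.Series:
    """Population proxy per neighborhood.

    ``literal`` (default): ``A_i · P_m`` (km²·persons), exactly as
    defined.  ``area_fraction``: ``(A_i / Σ_m A) · P_m`` — the
    municipality population shared out by area, in persons — for
    sensitivity analysis.
    """
    pops.require(nmap.municipalities)
    areas = nmap.areas_km2()
    if (areas <= 0).any():
        bad = areas.index[areas <= 0].tolist()
        raise ValueError(f"non-positive area for neighborhoods {bad[:5]}")
    muni = pd.Series({n.id: n.municipality for n in nmap})
    pm = muni.map(dict(pops.items()))
    if mode == "literal":
        proxy = areas * pm
    elif mode == "area_fraction":
        mun_area = areas.groupby(muni).transform("sum")
        proxy = areas / mun_area * pm
    else:
        raise ValueError(f"unknown proxy mode {mode!r}")
    return proxy.rename("proxy")


def quantile_bins(distances: np.ndarray, step: float = 0.05) -> np.ndarray:
    """Edges at the 0, step, …, 1 quantiles of the distance distribution.

    With the default step this yields exactly 20 half-open intervals
    [lo, hi), the last closed.  Raises if collapsing duplicates make any
    edge pair equal (degenerate distance distribution).
    """
    d = np.asarray(distances, dtype=float)
    n_bins = round(1.0 / step)
    if not np.isclose(n_bins * step, 1.0):
        raise ValueError("step must divide 1.0")
    edges = np.quantile(d, np.linspace(0.0, 1.0, n_bins + 1))
    if (np.diff(edges) <= 0).any():
        raise DegenerateStatisticError(
            "distance distribution too degenerate for quantile binning "
            "(duplicate quantile edges)")
    return edges


def bin_of(distances: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per distance: [lo, hi) intervals, last interval closed."""
    d = np.asarray(distances, dtype=float)
    idx = np.searchsorted(edges, d, side="right") - 1
    idx[d >= edges[-1]] = len(edges) - 2
    idx[d < edges[0]] = 0
    return idx


def spatial_G(h: pd.Series, pairs) -> float:
    """Evaluate G for one pair set against the global moments of *h*.

    *h* covers ALL neighborhoods (its mean/variance are the μ, σ² of the
    statistic); *pairs* is an iterable of (id, id) within-bin pairs.
    """
    mu = float(h.mean())
    sigma2 = float(((h - mu) ** 2).mean())  # population variance
    if sigma2 <= 0:
        raise DegenerateStatisticError("zero variance of per-capita counts")
    dev = h - mu
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair set")
    total = sum(float(dev[a]) * float(dev[b]) for a, b in pairs)
    return total / (len(pairs) * sigma2)


def yearly_counts(events: pd.DataFrame, nmap: NeighborhoodMap, year: int) -> pd.Series:
    """Event counts per neighborhood (all neighborhoods, zeros included)."""
    if "neighborhood_id" not in events.columns:
        raise ValueError("events must be mapped to neighborhoods first")
    counts = pd.Series(0.0, index=pd.Index(nmap.ids, name="neighborhood_id"))
    sel = events[pd.to_datetime(events["date"]).dt.year == year]
    if len(sel):
        got = sel.groupby("neighborhood_id").size()
        counts.loc[got.index] += got.astype(float)
    return counts


def spatial_curve(events: pd.DataFrame, nmap: NeighborhoodMap,
                  pops: MunicipalityTable, year: int,
                  step: float = 0.05, proxy_mode: str = "literal",
                  restrict_to_active: bool = False) -> pd.DataFrame:
    """The full G(t, r) curve for one year.

    Counts events per neighborhood, forms h = count / (A_i·P_m), computes
    global μ and σ², quantile-bins all pairwise centroid distances and
    evaluates G per bin.  Returns a DataFrame with columns
    ``year, r_lo_km, r_hi_km, n_pairs, G`` (bins with zero pairs omitted;
    with quantile bins every bin has pairs by construction).

    ``restrict_to_active`` recomputes moments and pairs over event-bearing
    neighborhoods only (sensitivity mode).
    """
    counts = yearly_counts(events, nmap, year)
    proxy = percapita_proxy(nmap, pops, mode=proxy_mode)
    h = counts / proxy
    keep = h.index if not restrict_to_active else h.index[counts > 0]
    if len(keep) < 2:
        raise DegenerateStatisticError("need at least two neighborhoods")
    h = h.loc[keep]
    mu = float(h.mean())
    sigma2 = float(((h - mu) ** 2).mean())
    if sigma2 <= 0:
        raise DegenerateStatisticError(
            f"zero variance of per-capita counts in year {year}")
    pair_ids, dists = pairwise_centroid_distances(nmap)
    if restrict_to_active:
        mask = np.array([a in set(keep) and b in set(keep) for a, b in pair_ids])
        pair_ids = [p for p, m in zip(pair_ids, mask) if m]
        dists = dists[mask]
    edges = quantile_bins(dists, step=step)
    bins = bin_of(dists, edges)
    dev = h.reindex([a for a, _ in pair_ids]).to_numpy() - mu
    dev2 = h.reindex([b for _, b in pair_ids]).to_numpy() - mu
    prod = dev * dev2
    n_bins = len(edges) - 1
    n_pairs = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=prod, minlength=n_bins)
    rows = []
    for b in range(n_bins):
        if n_pairs[b] == 0:
            continue
        rows.append({"year": year, "r_lo_km": edges[b], "r_hi_km": edges[b + 1],
                     "n_pairs": int(n_pairs[b]),
                     "G": sums[b] / (n_pairs[b] * sigma2)})
    return pd.DataFrame(rows)
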