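"""Weekly municipal casualty series, Pearson correlations and the
permutation null.

Weeks are consecutive Monday-anchored 7-day bins: the first bin starts on
the Monday on or before the study-window start.  Casualties (not event
counts) are summed per bin by default.  Significance of each pairwise
Pearson correlation coefficient (PCC) is assessed against a null built by
independently permuting every municipality's weekly vector ``n_iter``
times: Z = (observed PCC − null mean) / null sd, and pairs with Z > 3 are
flagged significant.  Note this null destroys autocorrelation as well as
cross-correlation; block or rotation nulls are a documented extension
point, not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geoio import MunicipalityTable, NeighborhoodMap


def monday_on_or_before(d) -> pd.Timestamp:
    ts = pd.Timestamp(d).normalize()
    return ts - pd.Timedelta(days=ts.weekday())


@dataclass
class WeeklyCountMatrix:
    """Municipality × week matrix of casualty sums (or rates).

    ``counts`` is indexed by municipality with integer week columns
    0..W−1; ``week_starts`` holds the Monday anchoring each bin.
    """

    counts: pd.DataFrame
    week_starts: pd.DatetimeIndex

    def __post_init__(self):
        if self.counts.shape[1] != len(self.week_starts):
            raise ValueError("counts width does not match week_starts")
        if (np.diff(self.week_starts.values).astype("timedelta64[D]")
                != np.timedelta64(7, "D")).any():
            raise ValueError("week bins must be consecutive 7-day intervals")

    @property
    def municipalities(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_weeks(self) -> int:
        return self.counts.shape[1]


def week_index_of(dates, anchor: pd.Timestamp) -> np.ndarray:
    """0-based Monday-anchored week bin of each date."""
    d = pd.to_datetime(pd.Series(dates)).dt.normalize()
    return ((d - anchor).dt.days // 7).to_numpy()


def weekly_aggregate(events: pd.DataFrame, nmap: NeighborhoodMap,
                     window: tuple | None = None,
                     value: str = "casualties") -> WeeklyCountMatrix:
    """Aggregate mapped events into the municipality × week matrix.

    *window* is an inclusive (start, end) date pair; defaults to the span
    of the event dates.  Every municipality in *nmap* appears, all-zero if
    silent.  ``value`` is ``"casualties"`` (default) or ``"events"``.
    """
    if "neighborhood_id" not in events.columns:
        raise ValueError("events must be mapped to neighborhoods first")
    if window is None:
        if events.empty:
            raise ValueError("empty window: no events and no explicit window")
        window = (events["date"].min(), events["date"].max())
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if end < start:
        raise ValueError("empty study window")
    anchor = monday_on_or_before(start)
    n_weeks = int((end.normalize() - anchor).days // 7) + 1
    week_starts = pd.DatetimeIndex([anchor + pd.Timedelta(days=7 * i)
                                    for i in range(n_weeks)])
    munis = nmap.municipalities
    mat = pd.DataFrame(0.0, index=pd.Index(munis, name="municipality"),
                       columns=range(n_weeks))
    if not events.empty:
        ev = events[(events["date"] >= anchor)
                    & (events["date"] < week_starts[-1] + pd.Timedelta(days=7))].copy()
        ev["week"] = week_index_of(ev["date"], anchor)
        ev["municipality"] = [nmap.municipality_of(nid)
                              for nid in ev["neighborhood_id"]]
        val = ev["casualties"] if value == "casualties" else pd.Series(1, index=ev.index)
        grouped = val.groupby([ev["municipality"], ev["week"]]).sum()
        for (m, w), v in grouped.items():
            mat.loc[m, w] += v
    return WeeklyCountMatrix(mat, week_starts)


def rate_per_100k(matrix: WeeklyCountMatrix, pops: MunicipalityTable) -> WeeklyCountMatrix:
    """Scale each municipality's vector to casualties per 100 000 people."""
    pops.require(matrix.municipalities)
    scaled = matrix.counts.copy().astype(float)
    for m in matrix.municipalities:
        scaled.loc[m] = scaled.loc[m] * (1e5 / pops[m])
    return WeeklyCountMatrix(scaled, matrix.week_starts)


def _pcc_all_pairs(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix with NaN rows for zero-variance series."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = np.nan
    corr[:, norms == 0] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)


def pcc_matrix(matrix: WeeklyCountMatrix) -> pd.DataFrame:
    """Observed PCC for every unordered municipality pair.

    Zero-variance series yield undefined (NaN) correlations, flagged via
    the ``undefined`` column rather than coerced to 0.
    """
    if matrix.n_weeks < 2 or len(matrix.municipalities) < 2:
        raise ValueError("need at least 2 weeks and 2 municipalities")
    values = matrix.counts.to_numpy(dtype=float)
    corr = _pcc_all_pairs(values)
    munis = matrix.municipalities
    rows = []
    for i in range(len(munis)):
        for j in range(i + 1, len(munis)):
            rows.append({"municipality_1": munis[i], "municipality_2": munis[j],
                         "pcc": corr[i, j], "undefined": bool(np.isnan(corr[i, j]))})
    return pd.DataFrame(rows)


def _null_pccs_pair(x: np.ndarray, y: np.ndarray, n_iter: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorised null PCCs for one pair: both vectors independently
    permuted each iteration."""
    W = len(x)
    xp = rng.permuted(np.broadcast_to(x, (n_iter, W)).copy(), axis=1)
    yp = rng.permuted(np.broadcast_to(y, (n_iter, W)).copy(), axis=1)
    xc = xp - xp.mean(axis=1, keepdims=True)
    yc = yp - yp.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def null_zscores(matrix: WeeklyCountMatrix, n_iter: int = 1000,
                 seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Permutation-null Z-scores for all municipality pairs.

    Each iteration independently reshuffles every municipality's weekly
    vector and recomputes all pairwise PCCs.  Returns a table with columns
    ``municipality_1, municipality_2, pcc, null_mean, null_sd, z,
    significant, undefined``, sorted by Z descending.  Pairs whose null sd
    is zero (or whose series have zero variance) are flagged undefined.
    Deterministic given *seed*.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    values = matrix.counts.to_numpy(dtype=float)
    munis = matrix.municipalities
    M, W = values.shape
    rng = np.random.default_rng(seed)
    obs = _pcc_all_pairs(values)

    if M == 2:
        nulls = _null_pccs_pair(values[0], values[1], n_iter, rng)
        finite = nulls[np.isfinite(nulls)]
        if len(finite) >= 2:
            null_mean = np.full((2, 2), finite.mean())
            null_sd = np.full((2, 2), finite.std(ddof=1))
        else:
            null_mean = np.full((2, 2), np.nan)
            null_sd = np.full((2, 2), np.nan)
    else:
        s = np.zeros((M, M))
        s2 = np.zeros((M, M))
        for _ in range(n_iter):
            perm = rng.permuted(values, axis=1)
            c = _pcc_all_pairs(perm)
            s += np.nan_to_num(c)
            s2 += np.nan_to_num(c) ** 2
        null_mean = s / n_iter
        null_sd = np.sqrt(np.maximum(s2 / n_iter - null_mean ** 2, 0.0)
                          * n_iter / (n_iter - 1))

    rows = []
    for i in range(M):
        for j in range(i + 1, M):
            pcc = obs[i, j]
            sd = null_sd[i, j]
            undefined = bool(np.isnan(pcc) or not sd > 0)
            z = np.nan if undefined else (pcc - null_mean[i, j]) / sd
            rows.append({"municipality_1": munis[i], "municipality_2": munis[j],
                         "pcc": pcc,
                         "null_mean": np.nan if undefined else null_mean[i, j],
                         "null_sd": np.nan if undefined else sd,
                         "z": z,
                         "significant": bool(not undefined and z > 3),
                         "undefined": undefined})
    out = pd.DataFrame(rows).sort_values("z", ascending=False, na_position="last")
    return out.reset_index(drop=True)


def write_correlation_table(table: pd.DataFrame, path) -> None:
    """Significance-ranked pair table as CSV."""
    cols = ["municipality_1", "municipality_2", "pcc", "z", "significant"]
    table[[c for c in cols if c in table.columns]].to_csv(path, index=False)


def correlation_square(table: pd.DataFrame, municipalities: list[str]) -> pd.DataFrame:
    """Heatmap-ready symmetric PCC matrix (diagonal = 1)."""
    sq = pd.DataFrame(np.eye(len(municipalities)),
                      index=municipalities, columns=municipalities)
    for _, r in table.iterrows():
        sq.loc[r["municipality_1"], r["municipality_2"]] = r["pcc"]
        sq.loc[r["municipality_2"], r["municipality_1"]] = r["pcc"]
    return sq
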