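"""Retrospective space-time permutation scan statistic.

The statistic evaluates every cylinder formed by crossing a circle of
data locations (grown around each location in order of distance, up to a
case-mass cap) with a month interval (up to a length cap). Under the
permutation null -- case months exchangeable with respect to locations --
the expected cylinder count factorizes from the marginals,

    mu = ns_circle * nt_interval / N,

and inference uses Monte Carlo replicates that permute month labels,
preserving both marginals exactly. The rank-based p-value of the maximum
is p = R/(S+1) where R counts replicates (plus the observation itself)
whose maximum is at least the observed maximum; replicate ties count
toward R, which is conservative.

Secondary clusters are the remaining cylinders in decreasing
log-likelihood-ratio order whose circles do not geometrically overlap a
previously kept circle; each is assigned a p-value against the same
distribution of replicate maxima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .injection import SimulatedDataset

__all__ = [
    "ScanConfig",
    "SpaceTimeCounts",
    "Cylinder",
    "DetectedCluster",
    "ScanResult",
    "tabulate",
    "log_glr",
    "expected_count",
    "enumerate_cylinders",
    "max_scan",
    "monte_carlo_p",
    "scan_dataset",
]


@dataclass(frozen=True)
class ScanConfig:
    """Settings of one scan analysis.

    Defaults follow the standard retrospective surveillance profile:
    monthly time aggregation, spatial window up to 50% of the cases,
    temporal window up to 50% of the study period, 999 Monte Carlo
    replications and significance at alpha = 0.05.
    """

    max_spatial_fraction: float = 0.5
    max_temporal_fraction: float = 0.5
    n_replications: int = 999
    alpha: float = 0.05
    time_aggregation: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_spatial_fraction <= 1.0:
            raise ValueError("max_spatial_fraction must lie in (0, 1]")
        if not 0.0 < self.max_temporal_fraction <= 1.0:
            raise ValueError("max_temporal_fraction must lie in (0, 1]")
        if self.n_replications < 1:
            raise ValueError("need at least one Monte Carlo replication")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.time_aggregation != 1:
            raise ValueError("only monthly time aggregation is supported")


@dataclass
class SpaceTimeCounts:
    """Case counts cross-tabulated by distinct location and month."""

    coords: np.ndarray  # (L, 2)
    n_st: np.ndarray  # (L, T) int64
    case_loc: np.ndarray  # (n_cases,) location index per case record

    @property
    def ns(self) -> np.ndarray:
        return self.n_st.sum(axis=1)

    @property
    def nt(self) -> np.ndarray:
        return self.n_st.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.n_st.sum())

    @property
    def n_locations(self) -> int:
        return self.n_st.shape[0]

    @property
    def n_months(self) -> int:
        return self.n_st.shape[1]


@dataclass(frozen=True)
class Cylinder:
    """One candidate cluster: a circle of locations x a month interval."""

    center_location: int
    n_locations: int  # locations included in the circle
    t_start: int
    t_end: int
    radius_km: float
    c: int  # observed count
    mu: float  # expected count under the permutation null
    log_glr: float

    @property
    def interval_length(self) -> int:
        return self.t_end - self.t_start + 1


@dataclass(frozen=True)
class DetectedCluster:
    """A reported cluster with Monte Carlo inference attached."""

    center_location: int
    center_xy: tuple[float, float]
    locations: np.ndarray = field(compare=False)
    t_start: int = 0
    t_end: int = 0
    radius_km: float = 0.0
    c: int = 0
    mu: float = 0.0
    log_glr: float = 0.0
    rr_estimate: float = 0.0
    p_value: float = 1.0
    rank_order: int = 1
    significant: bool = False

    @property
    def interval_length(self) -> int:
        return self.t_end - self.t_start + 1


@dataclass
class ScanResult:
    """Full output of one scan: ordered clusters and the null maxima."""

    clusters: list[DetectedCluster]
    maxima: np.ndarray  # replicate maxima (may exceed observed where truncated)
    counts: SpaceTimeCounts
    config: ScanConfig

    @property
    def primary(self) -> DetectedCluster | None:
        return self.clusters[0] if self.clusters else None

    @property
    def p_value(self) -> float:
        return self.primary.p_value if self.primary else 1.0

    def significant_clusters(self) -> list[DetectedCluster]:
        return [cl for cl in self.clusters if cl.significant]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": cl.rank_order,
                "center_id": cl.center_location,
                "center_x": cl.center_xy[0],
                "center_y": cl.center_xy[1],
                "radius_km": cl.radius_km,
                "t_start": cl.t_start,
                "t_end": cl.t_end,
                "n_locations": len(cl.locations),
                "observed": cl.c,
                "expected": cl.mu,
                "rr_estimate": cl.rr_estimate,
                "log_glr": cl.log_glr,
                "p_value": cl.p_value,
                "significant": cl.significant,
            }
            for cl in self.clusters
        ]
        return pd.DataFrame(rows)


def tabulate(
    dataset: SimulatedDataset | pd.DataFrame,
    n_months: int | None = None,
) -> SpaceTimeCounts:
    """Cross-tabulate case records by distinct coordinate tuple and month.

    Locations are the distinct (x, y) pairs present in the data (address
    points, or unit centroids after aggregation), ordered
    lexicographically so location ids are deterministic.
    """
    rec = dataset.records if isinstance(dataset, SimulatedDataset) else dataset
    if len(rec) == 0:
        raise ValueError("empty dataset")
    xy = np.column_stack([rec["x"].to_numpy(float), rec["y"].to_numpy(float)])
    coords, inverse = np.unique(xy, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    months = rec["month"].to_numpy(int)
    if n_months is None:
        n_months = int(months.max()) + 1
    if (months < 0).any() or (months >= n_months).any():
        raise ValueError("month index outside [0, n_months)")
    L = coords.shape[0]
    n_st = np.bincount(inverse * n_months + months, minlength=L * n_months)
    return SpaceTimeCounts(
        coords=coords,
        n_st=n_st.reshape(L, n_months).astype(np.int64),
        case_loc=inverse.astype(np.int32),
    )


def log_glr(c, mu, N):
    """Poisson generalized likelihood ratio in log space.

    Zero whenever c <= mu (no evidence of excess); +inf with a warning in
    the degenerate case mu = 0 with c > 0.
    """
    c = np.asarray(c, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    out = np.zeros(np.broadcast(c, mu).shape)
    degenerate = (mu == 0) & (c > 0)
    if degenerate.any():
        warnings.warn("cylinder with zero expectation but observed cases: "
                      "infinite evidence")
        out[degenerate] = np.inf
    excess = (c > mu) & ~degenerate
    if excess.any():
        cc, mm = c[excess], mu[excess]
        out[excess] = cc * np.log(cc / mm) + np.where(
            cc < N, (N - cc) * np.log((N - cc) / (N - mm)), 0.0
        )
    if out.ndim == 0:
        return float(out)
    return out


def expected_count(counts: SpaceTimeCounts, locations, t_start: int, t_end: int) -> float:
    """Permutation-model expectation mu = ns_circle * nt_interval / N."""
    ns = counts.ns[np.asarray(locations, int)].sum()
    nt = counts.nt[t_start : t_end + 1].sum()
    return float(ns * nt / counts.N)


def _geometry(counts: SpaceTimeCounts, config: ScanConfig):
    """Distance-ordered circles per center with the case-mass cap applied.

    Returns (order, kmax, sdist, t_max): for each center g, circles grow
    over order[g, :kmax[g]]; sdist[g, k] is the radius of the k-th circle.
    Singleton circles are always admitted, even above the cap. Distance
    ties break toward the lower location id.
    """
    coords = counts.coords
    ns = counts.ns
    N = counts.N
    L = coords.shape[0]
    cap = math.floor(config.max_spatial_fraction * N)
    d = np.sqrt(
        (coords[:, None, 0] - coords[None, :, 0]) ** 2
        + (coords[:, None, 1] - coords[None, :, 1]) ** 2
    )
    order_full = np.argsort(d, axis=1, kind="stable").astype(np.int32)
    cum = np.cumsum(ns[order_full], axis=1)
    kmax = np.maximum(1, (cum <= cap).sum(axis=1)).astype(np.int64)
    K = int(kmax.max())
    order = np.ascontiguousarray(order_full[:, :K])
    sdist = np.ascontiguousarray(np.take_along_axis(d, order_full[:, :K].astype(np.int64), axis=1))
    T = counts.n_months
    t_max = max(1, math.floor(config.max_temporal_fraction * T))
    return order, kmax, sdist, t_max


_EMPTY_I = np.empty(0, np.int64)
_EMPTY_F = np.empty(0, np.float64)

#: cell arrays above this size fall back to the table-based kernel
_CELL_LIMIT = 25_000_000
#: evidence floor of the streaming kernel's per-cell prune; any pass whose
#: maximum (or collect threshold) falls below this reruns unpruned
_GLR_FLOOR = 1.0
#: below this size the table-based kernel is just as fast and fully
#: double-precision; the streaming kernel stores single-precision logs
_CELL_MIN = 150_000


def _interval_layout(T: int, t_max: int):
    """Canonical (start, end) enumeration of month intervals: start
    ascending, end ascending within start — the kernel loop order."""
    starts, ends = [], []
    for s in range(T):
        for e in range(s + 1, min(T, s + t_max) + 1):
            starts.append(s)
            ends.append(e - 1)
    return np.asarray(starts, np.int32), np.asarray(ends, np.int32)


def _cell_data(counts: SpaceTimeCounts, geom):
    """Per-cylinder expectations, precomputed once per dataset.

    Month-permutation replicates preserve both marginals, so mu (hence
    log mu and log(N - mu)) is constant across all Monte Carlo passes;
    streaming these arrays sequentially keeps the scan kernel free of
    large random-access tables. Returns None when the cylinder set is
    too large to materialize (address-level data), in which case the
    table-based kernel is used instead.
    """
    order, kmax, sdist, t_max = geom
    T = counts.n_months
    int_start, int_end = _interval_layout(T, t_max)
    n_int = len(int_start)
    ns, nt, N = counts.ns, counts.nt, counts.N
    ntp = np.concatenate([[0], np.cumsum(nt)])
    nti = (ntp[int_end + 1] - ntp[int_start]).astype(np.int64)
    lognti = np.log(np.maximum(nti, 1))  # nti = 0 cells are always skipped
    logN = math.log(N)
    cmin = _kernels.cmin_table(N, _GLR_FLOOR)

    def _block(nsc):
        flat = np.multiply.outer(nsc, nti).ravel()
        cthr = cmin[flat].astype(np.int16)
        lmu = (np.log(nsc)[:, None] + lognti[None, :] - logN).ravel(
        ).astype(np.float32)
        lnmu = np.log(N - flat / N).astype(np.float32)
        return cthr, lmu, lnmu

    if (ns == 1).all() and (kmax == kmax[0]).all():
        # unit location masses (address data): per-cell tables depend
        # only on (circle size, interval) and are shared across centers
        cthr, lmu, lnmu = _block(np.arange(1, kmax[0] + 1, dtype=np.int64))
        return ("uniform", int(kmax[0]), t_max, cthr, lmu, lnmu)

    n_cells = int(kmax.sum()) * n_int
    if not _CELL_MIN <= n_cells <= _CELL_LIMIT:
        return None
    cthr = np.empty(n_cells, np.int16)  # skip cell while c <= cthr
    lmu = np.empty(n_cells, np.float32)
    lnmu = np.empty(n_cells, np.float32)
    pos = 0
    for g in range(counts.n_locations):
        ct, lm, ln = _block(np.cumsum(ns[order[g, : kmax[g]]]))
        span = ct.size
        cthr[pos : pos + span] = ct
        lmu[pos : pos + span] = lm
        lnmu[pos : pos + span] = ln
        pos += span
    return ("cells", t_max, cthr, lmu, lnmu)


_MU_FLOOR_CACHE: dict[int, np.ndarray] = {}


def _mu_floor_table(N: int) -> np.ndarray:
    """Threshold table realizing the bare c > mu test: floor(ns*nt/N)."""
    tab = _MU_FLOOR_CACHE.get(N)
    if tab is None:
        tab = (np.arange(N * N + 1, dtype=np.int64) // N).astype(np.int32)
        _MU_FLOOR_CACHE[N] = tab
    return tab


def _run_pass(counts, geom, cells=None, early_stop=np.inf, collect_thresh=np.inf,
              cap_out=0, exact=False):
    """One kernel pass.

    Both kernels normally prune cylinders whose evidence cannot reach
    the floor; if the pass maximum (or the collect threshold) falls
    below the floor, the pass reruns unpruned so results are exact in
    every case.
    """
    order, kmax, sdist, t_max = geom
    N = counts.N
    xlogx, logi, lognn = _kernels.glr_tables(N)
    if cap_out > 0:
        out = tuple(np.empty(cap_out, np.int64) for _ in range(5)) + (
            np.empty(cap_out, np.float64),
        )
    else:
        out = (_EMPTY_I,) * 5 + (_EMPTY_F,)
    use_exact = exact or collect_thresh < _GLR_FLOOR
    if use_exact:
        cells = None
    if cells is not None and cells[0] == "uniform":
        _tag, n_circles, ct_max, cthr, lmu, lnmu = cells
        res = _kernels.scan_pass_uniform(
            counts.n_st,
            order,
            n_circles,
            sdist,
            ct_max,
            cthr,
            lmu,
            lnmu,
            xlogx,
            N,
            early_stop,
            collect_thresh,
            *out,
        )
    elif cells is not None:
        _tag, ct_max, cthr, lmu, lnmu = cells
        res = _kernels.scan_pass_cells(
            counts.n_st,
            counts.ns,
            order,
            kmax,
            sdist,
            ct_max,
            cthr,
            lmu,
            lnmu,
            xlogx,
            N,
            early_stop,
            collect_thresh,
            *out,
        )
    else:
        cthr_tab = (
            _mu_floor_table(N)
            if use_exact
            else _kernels.cmin_table(N, _GLR_FLOOR)
        )
        res = _kernels.scan_pass(
            counts.n_st,
            counts.ns,
            counts.nt,
            order,
            kmax,
            sdist,
            t_max,
            cthr_tab,
            xlogx,
            logi,
            lognn,
            math.log(N),
            N,
            early_stop,
            collect_thresh,
            *out,
        )
    if not use_exact and res[0] < _GLR_FLOOR and res[0] <= early_stop:
        # pruned pass could have missed a sub-floor maximum: redo exactly
        return _run_pass(counts, geom, None, early_stop=early_stop,
                         collect_thresh=collect_thresh, cap_out=cap_out,
                         exact=True)
    return res, out


def enumerate_cylinders(counts: SpaceTimeCounts, config: ScanConfig):
    """Yield every candidate cylinder (reference-path generator).

    Intended for small instances, tests and didactic use; the scan itself
    evaluates the same cylinder set in a compiled kernel.
    """
    order, kmax, sdist, t_max = _geometry(counts, config)
    ns, nt, N = counts.ns, counts.nt, counts.N
    T = counts.n_months
    csum_t = np.concatenate([[0], np.cumsum(nt)])
    for g in range(counts.n_locations):
        cum = np.zeros(T, dtype=np.int64)
        nsc = 0
        for k in range(kmax[g]):
            loc = order[g, k]
            nsc += ns[loc]
            cum = cum + counts.n_st[loc]
            pref = np.concatenate([[0], np.cumsum(cum)])
            for s in range(T):
                for e in range(s + 1, min(T, s + t_max) + 1):
                    c = int(pref[e] - pref[s])
                    mu = nsc * (csum_t[e] - csum_t[s]) / N
                    yield Cylinder(
                        center_location=g,
                        n_locations=k + 1,
                        t_start=s,
                        t_end=e - 1,
                        radius_km=float(sdist[g, k]),
                        c=c,
                        mu=mu,
                        log_glr=log_glr(c, mu, N),
                    )


def _cylinder_from_raw(counts, geom, g, k, s, e, c) -> Cylinder:
    order, _kmax, sdist, _t_max = geom
    nsc = int(counts.ns[order[g, : k + 1]].sum())
    nti = int(counts.nt[s : e + 1].sum())
    mu = nsc * nti / counts.N
    return Cylinder(
        center_location=int(g),
        n_locations=int(k) + 1,
        t_start=int(s),
        t_end=int(e),
        radius_km=float(sdist[g, k]),
        c=int(c),
        mu=mu,
        log_glr=log_glr(c, mu, counts.N),
    )


def max_scan(counts: SpaceTimeCounts, config: ScanConfig) -> Cylinder | None:
    """The cylinder maximizing the log likelihood ratio.

    Ties break deterministically toward smaller radius, shorter interval,
    lower center id, earlier start. Returns None when no cylinder shows
    any excess (c > mu nowhere).
    """
    geom = _geometry(counts, config)
    cells = _cell_data(counts, geom)
    (best, g, k, s, e, c, _n), _ = _run_pass(counts, geom, cells)
    if g < 0:
        return None
    cyl = _cylinder_from_raw(counts, geom, g, k, s, e, c)
    # single-precision streaming kernels agree with the exact value to
    # well under this resolution; the returned Cylinder carries the
    # exact double-precision statistic
    assert abs(cyl.log_glr - best) < 5e-3
    return cyl


def _replicate_maxima(counts, geom, cells, config, rng, observed_max):
    """Maxima of S month-permutation replicates.

    Values are exact up to the observed maximum; a replicate whose
    running maximum exceeds the observed maximum stops early (its
    recorded value is a lower bound that is already above every
    reportable cluster, which is all rank comparisons need).
    """
    L, T = counts.n_st.shape
    months = np.repeat(np.arange(T), counts.nt)
    locs = np.repeat(np.arange(L), counts.ns)
    maxima = np.empty(config.n_replications)
    for r in range(config.n_replications):
        perm = rng.permutation(months)
        n_st = np.bincount(locs * T + perm, minlength=L * T).reshape(L, T)
        rep = SpaceTimeCounts(coords=counts.coords, n_st=n_st, case_loc=counts.case_loc)
        (best, *_), _ = _run_pass(rep, geom, cells, early_stop=observed_max)
        maxima[r] = best
    return maxima


def monte_carlo_p(counts: SpaceTimeCounts, config: ScanConfig, rng=None):
    """Monte Carlo rank p-value of the observed maximum.

    p = R/(S+1) with R = 1 + #{replicates whose max log GLR >= observed}.
    Also returns the replicate maxima.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geom = _geometry(counts, config)
    cells = _cell_data(counts, geom)
    (best, g, *_), _ = _run_pass(counts, geom, cells)
    maxima = _replicate_maxima(counts, geom, cells, config, rng, best)
    R = 1 + int((maxima >= best).sum())
    return R / (config.n_replications + 1), maxima


def scan_dataset(
    dataset: SimulatedDataset | SpaceTimeCounts,
    config: ScanConfig,
    n_months: int | None = None,
    rng=None,
) -> ScanResult:
    """Run the full analysis: maximize, permute, extract clusters."""
    if isinstance(dataset, SpaceTimeCounts):
        counts = dataset
    else:
        counts = tabulate(dataset, n_months=n_months)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geom = _geometry(counts, config)
    cells = _cell_data(counts, geom)
    (best, g, k, s, e, c, _n), _ = _run_pass(counts, geom, cells)
    if g < 0:
        return ScanResult(clusters=[], maxima=np.zeros(config.n_replications),
                          counts=counts, config=config)
    maxima = _replicate_maxima(counts, geom, cells, config, rng, best)
    clusters = extract_clusters(counts, geom, config, best, maxima, cells)
    return ScanResult(clusters=clusters, maxima=maxima, counts=counts, config=config)


def _significance_threshold(maxima, config):
    """Smallest log GLR that could still be significant at alpha.

    p <= alpha requires 1 + #{maxima >= glr} <= alpha (S + 1); when even
    rank 1 cannot reach alpha the threshold is infinite.
    """
    S = config.n_replications
    allowed = math.floor(config.alpha * (S + 1)) - 1  # max permissible count
    if allowed < 0:
        return np.inf
    desc = np.sort(maxima)[::-1]
    if allowed >= len(desc):
        return 0.0
    # need #{maxima >= glr} <= allowed, i.e. glr strictly above the
    # (allowed+1)-th largest replicate maximum
    return float(desc[allowed])


def extract_clusters(counts, geom, config, observed_max, maxima, cells=None) -> list[DetectedCluster]:
    """Greedy non-overlapping clusters, best evidence first.

    Reported clusters are those with p <= alpha, plus the primary
    regardless of significance (flagged). Candidate cylinders below the
    significance threshold cannot enter the report and cannot block a
    higher-scoring cylinder, so only cylinders at or above
    min(threshold, observed max) are materialized.
    """
    thresh = min(_significance_threshold(maxima, config), observed_max)
    cap = 200_000
    while True:
        (best, g, k, s, e, c, n_coll), out = _run_pass(
            counts, geom, cells, collect_thresh=thresh, cap_out=cap
        )
        if n_coll <= cap:
            break
        cap = 2 * n_coll
    out_g, out_k, out_s, out_e, out_c, out_glr = (a[:n_coll] for a in out)

    order, _kmax, sdist, _t_max = geom
    radius = sdist[out_g, out_k]
    tlen = out_e - out_s + 1
    sortkey = np.lexsort((out_s, out_g, tlen, radius, -out_glr))
    out_g, out_k, out_s, out_e, out_c, out_glr, radius = (
        a[sortkey] for a in (out_g, out_k, out_s, out_e, out_c, out_glr, radius)
    )
    cx = counts.coords[out_g, 0]
    cy = counts.coords[out_g, 1]
    kept = _kernels.greedy_nonoverlap(cx, cy, radius, out_g.astype(np.int64), 1000)

    desc = np.sort(maxima)  # ascending; count >= via searchsorted
    S = config.n_replications
    clusters: list[DetectedCluster] = []
    for j, i in enumerate(kept):
        glr = float(out_glr[i])
        n_ge = S - int(np.searchsorted(desc, glr, side="left"))
        p = (1 + n_ge) / (S + 1)
        significant = p <= config.alpha
        if j > 0 and not significant:
            continue
        rank = len(clusters) + 1
        gi, ki = int(out_g[i]), int(out_k[i])
        locs = order[gi, : ki + 1].astype(np.int64)
        nsc = int(counts.ns[locs].sum())
        nti = int(counts.nt[out_s[i] : out_e[i] + 1].sum())
        mu = nsc * nti / counts.N
        clusters.append(
            DetectedCluster(
                center_location=gi,
                center_xy=(float(counts.coords[gi, 0]), float(counts.coords[gi, 1])),
                locations=locs,
                t_start=int(out_s[i]),
                t_end=int(out_e[i]),
                radius_km=float(radius[i]),
                c=int(out_c[i]),
                mu=mu,
                log_glr=glr,
                rr_estimate=float(out_c[i] / mu) if mu > 0 else np.inf,
                p_value=p,
                rank_order=rank,
                significant=significant,
            )
        )
    return clusters
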