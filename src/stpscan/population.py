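"""Synthetic at-risk population and areal-unit systems.

The study design needs three ingredients that stand in for a geocoded
administrative-claims population: a spatially heterogeneous pool of
candidate background cases on a planar Tennessee-sized rectangle, a
seasonally varying monthly case distribution over a multi-year study
period, and two independent areal-unit partitions of the region (a fine
ZIP-like system and a coarse county-like system) with centroids used for
spatial aggregation.

All coordinates are planar kilometres; distances throughout the package
are Euclidean.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger(__name__)

#: stage codes used to derive named child seeds from a master seed
_STAGE_CODES = {
    "blobs": 11,
    "points": 13,
    "months": 17,
    "zip_units": 19,
    "county_units": 23,
}


def child_seed(master_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Derive a named, order-independent child seed from a master seed."""
    code = _STAGE_CODES.get(stage)
    if code is None:
        # stable fallback for ad-hoc stage names
        code = sum(ord(ch) for ch in stage) % 1009 + 1000
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, code, int(index)])


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic study region and background pool.

    Defaults emulate the published study's setting: a 700 x 180 km
    rectangle (Tennessee-like aspect ratio), a pool of 122,500 candidate
    cases over 48 months with a winter seasonal peak, and 617 ZIP-like /
    95 county-like areal units.
    """

    width_km: float = 700.0
    height_km: float = 180.0
    n_pool: int = 122_500
    n_blobs: int = 6
    blob_weight: float = 0.65
    months: int = 48
    seasonal_amplitude: float = 0.5
    peak_month: int = 0  # January
    n_zip_units: int = 617
    n_county_units: int = 95
    seed: int = 0
    # optional explicit blob geometry; drawn from the seed when None
    blob_centers: tuple[tuple[float, float], ...] | None = None
    blob_sigmas_km: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.width_km <= 0 or self.height_km <= 0:
            raise ValueError("region dimensions must be positive")
        if self.n_pool <= 0:
            raise ValueError("n_pool must be positive")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be non-negative")
        if not 0.0 <= self.blob_weight <= 1.0:
            raise ValueError("blob_weight must lie in [0, 1]")
        if self.months < 4:
            raise ValueError("months must be >= 4 (need a 3-month window)")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must lie in [0, 1)")
        if not (self.n_zip_units > self.n_county_units >= 1):
            raise ValueError("need n_zip_units > n_county_units >= 1")
        if self.blob_sigmas_km is not None:
            if any(s <= 0 for s in self.blob_sigmas_km):
                raise ValueError("blob sigmas must be positive")
        if self.blob_centers is not None:
            for cx, cy in self.blob_centers:
                if not (0 <= cx <= self.width_km and 0 <= cy <= self.height_km):
                    raise ValueError("blob centers must lie inside the region")

    def replace(self, **kw) -> "RegionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PopulationFrame:
    """Background case pool: coordinates, months and areal assignments.

    The pool doubles as the at-risk population: the inside-cluster
    proportion ``C`` is computed against it and control cases are drawn
    from it, which makes the null hypothesis exactly exchangeable.
    """

    x: np.ndarray
    y: np.ndarray
    month: np.ndarray
    month_marginal: np.ndarray
    config: RegionConfig
    zip_id: np.ndarray | None = None
    county_id: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {"x": self.x, "y": self.y, "month": self.month}
        if self.zip_id is not None:
            cols["zip_id"] = self.zip_id
        if self.county_id is not None:
            cols["county_id"] = self.county_id
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ArealUnitSystem:
    """A partition of the region into Voronoi cells around seed points.

    ``seeds`` are retained so that new points (e.g. synthesized treatment
    cases) can be assigned to units with the same nearest-seed rule that
    partitioned the pool.
    """

    level: str  # "zip" or "county"
    seeds: np.ndarray  # (n_units, 2) Voronoi generators
    centroids: np.ndarray  # (n_units, 2) mean of member points
    member_count: np.ndarray  # (n_units,)
    _tree: cKDTree = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._tree is None:
            self._tree = cKDTree(self.seeds)

    @property
    def n_units(self) -> int:
        return self.seeds.shape[0]

    def assign(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-seed unit id for arbitrary planar points."""
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        return self._tree.query(pts)[1].astype(np.int32)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": np.arange(self.n_units),
                "level": self.level,
                "cx": self.centroids[:, 0],
                "cy": self.centroids[:, 1],
                "member_count": self.member_count,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_centroid_table(cls, df: pd.DataFrame, level: str) -> "ArealUnitSystem":
        """Build a unit system from user-supplied centroids (CSV escape
        hatch for real geographies); seeds are taken to be the centroids."""
        pts = df[["cx", "cy"]].to_numpy(float)
        counts = df["member_count"].to_numpy() if "member_count" in df else np.ones(len(df), int)
        return cls(level=level, seeds=pts, centroids=pts.copy(), member_count=counts)


def month_distribution(config: RegionConfig) -> np.ndarray:
    """Seasonal multinomial over study months.

    Relative weight of month m is 1 + A*cos(2*pi*((m mod 12) - peak)/12),
    normalized over all months; A = 0 gives the uniform distribution.
    """
    m = np.arange(config.months)
    w = 1.0 + config.seasonal_amplitude * np.cos(
        2.0 * np.pi * ((m % 12) - config.peak_month) / 12.0
    )
    return w / w.sum()


def _draw_blob_geometry(config: RegionConfig, rng: np.random.Generator):
    if config.n_blobs == 0:
        return np.empty((0, 2)), np.empty(0), np.empty(0)
    if config.blob_centers is not None:
        centers = np.asarray(config.blob_centers, float)
    else:
        # keep population centers away from the region edge
        mx, my = 0.05 * config.width_km, 0.1 * config.height_km
        centers = np.column_stack(
            [
                rng.uniform(mx, config.width_km - mx, config.n_blobs),
                rng.uniform(my, config.height_km - my, config.n_blobs),
            ]
        )
    if config.blob_sigmas_km is not None:
        sigmas = np.asarray(config.blob_sigmas_km, float)
    else:
        sigmas = rng.uniform(4.0, 18.0, config.n_blobs)
    if centers.shape[0] != config.n_blobs or sigmas.shape[0] != config.n_blobs:
        raise ValueError("blob geometry must match n_blobs")
    # heavy-tailed city sizes: mass proportional to 1/rank
    weights = 1.0 / np.arange(1, config.n_blobs + 1)
    weights = weights / weights.sum()
    return centers, sigmas, weights


def generate_population(config: RegionConfig) -> PopulationFrame:
    """Draw the background case pool.

    Points come from a mixture of isotropic Gaussian "city" blobs
    (total mass ``blob_weight``) and a uniform background over the
    rectangle; Gaussian draws falling outside the rectangle are resampled.
    Each point receives a month drawn from the seasonal distribution.
    Fully determined by ``config.seed``.
    """
    rng_blobs = np.random.default_rng(child_seed(config.seed, "blobs"))
    centers, sigmas, bweights = _draw_blob_geometry(config, rng_blobs)

    rng = np.random.default_rng(child_seed(config.seed, "points"))
    n = config.n_pool
    n_blob_pts = rng.binomial(n, config.blob_weight) if config.n_blobs > 0 else 0
    xs = np.empty(n)
    ys = np.empty(n)

    # uniform background
    n_bg = n - n_blob_pts
    xs[:n_bg] = rng.uniform(0.0, config.width_km, n_bg)
    ys[:n_bg] = rng.uniform(0.0, config.height_km, n_bg)

    if n_blob_pts > 0:
        which = rng.choice(config.n_blobs, size=n_blob_pts, p=bweights)
        bx = rng.normal(centers[which, 0], sigmas[which])
        by = rng.normal(centers[which, 1], sigmas[which])
        # resample out-of-region draws until all fall inside
        bad = ~(
            (bx >= 0) & (bx <= config.width_km) & (by >= 0) & (by <= config.height_km)
        )
        while bad.any():
            idx = np.flatnonzero(bad)
            w = which[idx]
            bx[idx] = rng.normal(centers[w, 0], sigmas[w])
            by[idx] = rng.normal(centers[w, 1], sigmas[w])
            bad[idx] = ~(
                (bx[idx] >= 0)
                & (bx[idx] <= config.width_km)
                & (by[idx] >= 0)
                & (by[idx] <= config.height_km)
            )
        xs[n_bg:] = bx
        ys[n_bg:] = by

    marginal = month_distribution(config)
    rng_m = np.random.default_rng(child_seed(config.seed, "months"))
    months = rng_m.choice(config.months, size=n, p=marginal).astype(np.int16)

    return PopulationFrame(x=xs, y=ys, month=months, month_marginal=marginal, config=config)


def build_areal_units(
    pop: PopulationFrame,
    level: str,
    n_units: int | None = None,
    seed: int | None = None,
    drop_empty: bool = True,
) -> ArealUnitSystem:
    """Partition the pool into Voronoi cells around k-means++ seeds.

    Seeds are placed on the point cloud with the k-means++ strategy (so
    unit density follows population density, as real ZIP codes do) and
    every point is assigned to its nearest seed. A unit that ends up
    empty is reseeded once at a random member-less point; if it is still
    empty it is dropped with a warning (or an error if ``drop_empty`` is
    False). The unit centroid is the arithmetic mean of member points.
    """
    if level not in ("zip", "county"):
        raise ValueError("level must be 'zip' or 'county'")
    if n_units is None:
        n_units = pop.config.n_zip_units if level == "zip" else pop.config.n_county_units
    if seed is None:
        seed = pop.config.seed
    pts = np.column_stack([pop.x, pop.y])
    if n_units > len(pts):
        raise ValueError("n_units exceeds number of points")

    ss = child_seed(seed, f"{level}_units")
    rint = int(np.random.default_rng(ss).integers(0, 2**31 - 1))
    seeds, _ = kmeans_plusplus(pts, n_clusters=n_units, random_state=rint)

    tree = cKDTree(seeds)
    assign = tree.query(pts)[1]
    counts = np.bincount(assign, minlength=n_units)

    if (counts == 0).any():
        # reseed empty units once at random points, then drop leftovers
        rng = np.random.default_rng(ss.spawn(1)[0])
        empty = np.flatnonzero(counts == 0)
        seeds[empty] = pts[rng.choice(len(pts), size=len(empty), replace=False)]
        tree = cKDTree(seeds)
        assign = tree.query(pts)[1]
        counts = np.bincount(assign, minlength=n_units)
        if (counts == 0).any():
            still = np.flatnonzero(counts == 0)
            if not drop_empty:
                raise RuntimeError(f"{len(still)} empty {level} units after reseeding")
            logger.warning("dropping %d empty %s units", len(still), level)
            warnings.warn(f"dropping {len(still)} empty {level} units")
            keep = np.flatnonzero(counts > 0)
            seeds = seeds[keep]
            tree = cKDTree(seeds)
            assign = tree.query(pts)[1]
            counts = np.bincount(assign, minlength=len(keep))
            n_units = len(keep)

    centroids = np.zeros((n_units, 2))
    np.add.at(centroids[:, 0], assign, pop.x)
    np.add.at(centroids[:, 1], assign, pop.y)
    centroids /= counts[:, None]

    system = ArealUnitSystem(
        level=level, seeds=seeds, centroids=centroids, member_count=counts
    )
    if level == "zip":
        pop.zip_id = assign.astype(np.int32)
    else:
        pop.county_id = assign.astype(np.int32)
    return system


def build_study_region(config: RegionConfig):
    """Convenience: population plus both areal-unit systems."""
    pop = generate_population(config)
    zips = build_areal_units(pop, "zip")
    counties = build_areal_units(pop, "county")
    return pop, zips, counties
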