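"""Artificial space-time cluster injection.

Each simulated dataset holds exactly 1000 case records: ``N_t``
"treatment" cases placed uniformly inside a square cluster during a
3-month onset window, and ``N_c = 1000 - N_t`` "control" cases drawn
from the background pool with their true coordinates but re-randomized
months. The treatment count is binomial with success probability ``p``
chosen so that the expected observed/expected ratio inside the square
equals the target relative risk RR:

    C  = share of the at-risk pool inside the square
    p  = C (RR - 1) / (1 - C)      (clamped to 1; p = 0 when RR = 1)
    N_t ~ Binomial(1000, p)

With this choice the expected inside-square count is
N_t + C*N_c = 1000*C*RR, i.e. RR times the no-excess expectation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


logger = logging.getLogger(__name__)

N_CASES = 1000  # records per simulated dataset
WINDOW_MONTHS = 3  # temporal length of the injected cluster
R_MIN_KM = 1.6
R_MAX_KM = 48.0


@dataclass(frozen=True)
class ArtificialCluster:
    """Ground truth for one simulated dataset.

    The cluster region is a square of side ``2 * r_km`` (``r_km`` is the
    radius of the inscribed circle) centred at ``center``; the cluster
    window is the 3 months starting at ``onset_month``.
    """

    center: tuple[float, float]
    r_km: float
    rr: int
    onset_month: int
    C: float
    p: float
    n_t: int
    n_c: int

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def window(self) -> tuple[int, int]:
        return (self.onset_month, self.onset_month + WINDOW_MONTHS - 1)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return (np.abs(np.asarray(x) - cx) <= self.r_km) & (
            np.abs(np.asarray(y) - cy) <= self.r_km
        )

    def to_dict(self) -> dict:
        return {
            "center_x": self.center[0],
            "center_y": self.center[1],
            "r_km": self.r_km,
            "rr": self.rr,
            "onset_month": self.onset_month,
            "C": self.C,
            "p": self.p,
            "n_t": self.n_t,
            "n_c": self.n_c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArtificialCluster":
        return cls(
            center=(float(d["center_x"]), float(d["center_y"])),
            r_km=float(d["r_km"]),
            rr=int(d["rr"]),
            onset_month=int(d["onset_month"]),
            C=float(d["C"]),
            p=float(d["p"]),
            n_t=int(d["n_t"]),
            n_c=int(d["n_c"]),
        )


@dataclass
class SimulatedDataset:
    """1000 case records at one spatial resolution plus their truth."""

    records: pd.DataFrame  # case_id, x, y, month, is_treatment, zip_id, county_id
    truth: ArtificialCluster
    resolution: str = "address"

    def __post_init__(self) -> None:
        if len(self.records) != self.truth.n_t + self.truth.n_c:
            raise ValueError("record count inconsistent with truth counts")

    @property
    def n(self) -> int:
        return len(self.records)

    def copy_with(self, records: pd.DataFrame, resolution: str) -> "SimulatedDataset":
        return SimulatedDataset(records=records, truth=self.truth, resolution=resolution)


def draw_cluster_geometry(
    pop: PopulationFrame,
    seed,
    r_range: tuple[float, float] = (R_MIN_KM, R_MAX_KM),
    rr_values=range(1, 11),
):
    """Draw (center, r_km, RR, onset_month) for one artificial cluster.

    r is uniform on ``r_range``; the square is placed uniformly among
    positions that keep it entirely inside the region; RR is uniform on
    ``rr_values``; the 3-month onset is uniform over feasible months.
    """
    cfg = pop.config
    lo, hi = r_range
    if not (R_MIN_KM <= lo <= hi <= R_MAX_KM):
        raise ValueError(f"r_range must lie within [{R_MIN_KM}, {R_MAX_KM}]")
    if cfg.width_km < 2 * R_MAX_KM or cfg.height_km < 2 * R_MAX_KM:
        raise ValueError("region too small to contain the largest cluster square")
    rng = np.random.default_rng(seed)
    r = rng.uniform(lo, hi)
    cx = rng.uniform(r, cfg.width_km - r)
    cy = rng.uniform(r, cfg.height_km - r)
    rr = int(rng.choice(np.asarray(list(rr_values), dtype=int)))
    onset = int(rng.integers(0, cfg.months - WINDOW_MONTHS + 1))
    return (cx, cy), float(r), rr, onset


def compute_C(pop: PopulationFrame, center, r_km: float) -> float:
    """Share of the at-risk pool inside the square ``|x-cx|,|y-cy| <= r``."""
    cx, cy = center
    inside = (np.abs(pop.x - cx) <= r_km) & (np.abs(pop.y - cy) <= r_km)
    C = inside.sum() / pop.n
    if C == 0.0:
        warnings.warn("cluster square contains no at-risk mass (C = 0); p will be 0")
    return float(C)


def compute_p(C: float, rr: int) -> tuple[float, float]:
    """Excess inside-probability p and its complement q = 1 - p."""
    if not 0.0 <= C <= 1.0:
        raise ValueError("C must lie in [0, 1]")
    if rr < 1:
        raise ValueError("RR must be >= 1")
    if rr == 1:
        return 0.0, 1.0
    if C == 1.0:
        return 1.0, 0.0
    raw = C * (rr - 1) / (1.0 - C)
    if raw > 1.0:
        logger.info("p clamped to 1 (C=%.4f, RR=%d, raw=%.3f)", C, rr, raw)
    p = min(1.0, raw)
    return p, 1.0 - p


def draw_counts(p: float, seed, n_total: int = N_CASES) -> tuple[int, int]:
    """Treatment/control split: N_t ~ Binomial(n_total, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_t = int(rng.binomial(n_total, p))
    return n_t, n_total - n_t


def sample_controls(pop: PopulationFrame, n_c: int, seed) -> pd.DataFrame:
    """Draw control cases from the pool without replacement.

    Coordinates and unit assignments are retained; each control's month
    is re-drawn i.i.d. from the pool's month distribution, which removes
    any space-time interaction while preserving the purely spatial and
    purely temporal structure of the population.
    """
    if n_c > pop.n:
        raise ValueError("cannot sample more controls than pool points")
    if pop.zip_id is None or pop.county_id is None:
        raise ValueError("population lacks areal-unit assignments")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pop.n, size=n_c, replace=False)
    months = rng.choice(pop.config.months, size=n_c, p=pop.month_marginal)
    return pd.DataFrame(
        {
            "x": pop.x[idx],
            "y": pop.y[idx],
            "month": months.astype(np.int16),
            "is_treatment": np.zeros(n_c, dtype=bool),
            "zip_id": pop.zip_id[idx],
            "county_id": pop.county_id[idx],
        }
    )


def sample_treatments(
    truth: ArtificialCluster,
    zip_units: ArealUnitSystem,
    county_units: ArealUnitSystem,
    seed,
) -> pd.DataFrame:
    """Place N_t treatment cases uniformly in the square, months uniform
    over the 3-month window; areal-unit ids come from the same
    nearest-seed rule that partitioned the pool."""
    rng = np.random.default_rng(seed)
    n_t = truth.n_t
    cx, cy = truth.center
    x = rng.uniform(cx - truth.r_km, cx + truth.r_km, n_t)
    y = rng.uniform(cy - truth.r_km, cy + truth.r_km, n_t)
    months = truth.onset_month + rng.integers(0, WINDOW_MONTHS, n_t)
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "month": months.astype(np.int16),
            "is_treatment": np.ones(n_t, dtype=bool),
            "zip_id": zip_units.assign(x, y),
            "county_id": county_units.assign(x, y),
        }
    )


def assemble_dataset(
    controls: pd.DataFrame,
    treatments: pd.DataFrame,
    truth: ArtificialCluster,
    seed,
) -> SimulatedDataset:
    """Concatenate, shuffle, and attach stable case ids."""
    if len(controls) != truth.n_c or len(treatments) != truth.n_t:
        raise ValueError("control/treatment counts do not match truth")
    rng = np.random.default_rng(seed)
    rec = pd.concat([controls, treatments], ignore_index=True)
    order = rng.permutation(len(rec))
    rec = rec.iloc[order].reset_index(drop=True)
    rec.insert(0, "case_id", np.arange(len(rec), dtype=np.int32))
    return SimulatedDataset(records=rec, truth=truth, resolution="address")


def inject_dataset(
    pop: PopulationFrame,
    zip_units: ArealUnitSystem,
    county_units: ArealUnitSystem,
    seed: int,
    r_range: tuple[float, float] = (R_MIN_KM, R_MAX_KM),
    rr_values=range(1, 11),
) -> SimulatedDataset:
    """Full injection pipeline for one address-level dataset.

    All randomness flows through named children of ``seed`` so datasets
    are reproducible individually and independent of generation order.
    """
    s_geom, s_counts, s_ctrl, s_trt, s_shuffle = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 101]
    ).spawn(5)
    center, r, rr, onset = draw_cluster_geometry(pop, s_geom, r_range, rr_values)
    C = compute_C(pop, center, r)
    p, _q = compute_p(C, rr)
    n_t, n_c = draw_counts(p, s_counts)
    truth = ArtificialCluster(
        center=center, r_km=r, rr=rr, onset_month=onset, C=C, p=p, n_t=n_t, n_c=n_c
    )
    controls = sample_controls(pop, n_c, s_ctrl)
    treatments = sample_treatments(truth, zip_units, county_units, s_trt)
    return assemble_dataset(controls, treatments, truth, s_shuffle)
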