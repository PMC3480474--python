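"""End-to-end experiment: population -> injection -> aggregation -> scan
-> metrics, reproducibly from one configuration.

Matched-triplet discipline: each dataset index produces ONE address-level
dataset whose ZIP and county versions are deterministic centroid
transforms of the same records, so spatial resolution is the only factor
that varies between the arms of a comparison. Every dataset derives its
own child seeds from (master_seed, dataset index, stage), making results
independent of completion order and safely resumable.

The desk-scale default (300 datasets, 199 replications) keeps a full run
on one CPU in minutes; :meth:`ExperimentConfig.full_scale` switches to
the full design of 10,000 datasets per resolution with 999 replications.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import at_resolution
from .injection import R_MAX_KM, R_MIN_KM, inject_dataset
from .metrics import evaluate_dataset, metrics_table, resolution_summary
from .population import RegionConfig, build_study_region
from .scan import ScanConfig, scan_dataset

logger = logging.getLogger(__name__)

OUTCOME_FILE = "outcomes.csv"
MANIFEST_FILE = "manifest.json"
METRICS_FILE = "metrics.csv"


@dataclass(frozen=True)
class ExperimentConfig:
    region: RegionConfig = field(default_factory=RegionConfig)
    scan: ScanConfig = field(default_factory=lambda: ScanConfig(n_replications=199))
    n_datasets: int = 300
    resolutions: tuple[str, ...] = ("address", "zip", "county")
    master_seed: int = 0
    output_dir: str | None = None
    r_range: tuple[float, float] = (R_MIN_KM, R_MAX_KM)
    rr_values: tuple[int, ...] = tuple(range(1, 11))
    membership: str = "space_time"
    estimator: str = "pooled"

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not self.resolutions:
            raise ValueError("resolutions must be non-empty")
        for r in self.resolutions:
            if r not in ("address", "zip", "county"):
                raise ValueError(f"unknown resolution {r!r}")

    @classmethod
    def full_scale(cls, **kw) -> "ExperimentConfig":
        kw.setdefault("n_datasets", 10_000)
        kw.setdefault("scan", ScanConfig(n_replications=999))
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = dataclasses.asdict(self.region)
        d["scan"] = dataclasses.asdict(self.scan)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        region = d.pop("region", {})
        if region.get("blob_centers") is not None:
            region["blob_centers"] = tuple(tuple(c) for c in region["blob_centers"])
        if region.get("blob_sigmas_km") is not None:
            region["blob_sigmas_km"] = tuple(region["blob_sigmas_km"])
        scan = d.pop("scan", {})
        d["resolutions"] = tuple(d.get("resolutions", ("address", "zip", "county")))
        d["r_range"] = tuple(d.get("r_range", (R_MIN_KM, R_MAX_KM)))
        d["rr_values"] = tuple(d.get("rr_values", tuple(range(1, 11))))
        return cls(region=RegionConfig(**region), scan=ScanConfig(**scan), **d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _dataset_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, 2, int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _scan_rng(master: int, index: int, resolution: str) -> np.random.Generator:
    code = {"address": 0, "zip": 1, "county": 2}[resolution]
    return np.random.default_rng(
        np.random.SeedSequence([int(master) & 0x7FFFFFFF, 3, int(index), code])
    )


def run_one(config: ExperimentConfig, pop, zips, counties, index: int) -> list[dict]:
    """Inject dataset ``index``, scan it at every configured resolution."""
    address = inject_dataset(
        pop, zips, counties, seed=_dataset_seed(config.master_seed, index),
        r_range=config.r_range, rr_values=config.rr_values,
    )
    rows = []
    for res in config.resolutions:
        ds = at_resolution(address, res, zips, counties)
        result = scan_dataset(
            ds, config.scan, n_months=config.region.months,
            rng=_scan_rng(config.master_seed, index, res),
        )
        rows.append(
            evaluate_dataset(result, ds, membership=config.membership, dataset_id=index)
        )
    return rows


def _write_manifest(run_dir: Path, config: ExperimentConfig) -> None:
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash()}
    (run_dir / MANIFEST_FILE).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_manifest(run_dir: Path) -> ExperimentConfig:
    path = run_dir / MANIFEST_FILE
    if not path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(path.read_text())
    config = ExperimentConfig.from_dict(manifest["config"])
    if config.config_hash() != manifest.get("config_hash"):
        raise RuntimeError("manifest config hash mismatch; refusing to resume")
    return config


def run_experiment(
    config: ExperimentConfig,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full study; returns (metrics table, outcome rows).

    With ``config.output_dir`` set, outcomes stream to disk after each
    dataset and the run can be resumed with :func:`resume`.
    """
    run_dir = Path(config.output_dir) if config.output_dir else None
    done: set[int] = set()
    prior: list[pd.DataFrame] = []
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        manifest = run_dir / MANIFEST_FILE
        if manifest.exists():
            existing = _load_manifest(run_dir)
            if existing.config_hash() != config.config_hash():
                raise RuntimeError("output_dir holds a different experiment")
            out_path = run_dir / OUTCOME_FILE
            if out_path.exists():
                df = pd.read_csv(out_path)
                done = set(df["dataset_id"].astype(int))
                prior.append(df)
        else:
            _write_manifest(run_dir, config)

    pop, zips, counties = build_study_region(config.region)
    rows: list[dict] = []
    for i in range(config.n_datasets):
        if i in done:
            continue
        try:
            new = run_one(config, pop, zips, counties, i)
        except Exception:
            logger.exception(
                "dataset %d failed (seed %d)", i, _dataset_seed(config.master_seed, i)
            )
            raise
        rows.extend(new)
        if run_dir is not None:
            out_path = run_dir / OUTCOME_FILE
            pd.DataFrame(new).to_csv(
                out_path, mode="a", header=not out_path.exists(), index=False
            )
        if progress and (i + 1) % 25 == 0:
            logger.info("completed %d/%d datasets", i + 1, config.n_datasets)

    outcomes = pd.concat(prior + [pd.DataFrame(rows)], ignore_index=True) if rows or prior else pd.DataFrame(rows)
    outcomes = outcomes.sort_values(["dataset_id", "resolution"]).reset_index(drop=True)
    table = metrics_table(outcomes, estimator=config.estimator)
    if run_dir is not None:
        table.to_csv(run_dir / METRICS_FILE, index=False)
        if "address" in config.resolutions and len(config.resolutions) > 1:
            resolution_summary(outcomes, config.estimator).to_csv(
                run_dir / "resolution_summary.csv", index=False
            )
        from .metrics import plot_metric_curves

        for metric in ("power", "psp", "sensitivity", "ppv"):
            plot_metric_curves(table, metric, run_dir / f"{metric}.png")
    return table, outcomes


def resume(run_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Continue an interrupted run; completed dataset indices are skipped
    and the final results equal those of an uninterrupted run."""
    run_dir = Path(run_dir)
    config = _load_manifest(run_dir)
    config = dataclasses.replace(config, output_dir=str(run_dir))
    return run_experiment(config)
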