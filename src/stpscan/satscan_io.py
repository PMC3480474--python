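"""Readers/writers for SaTScan-style case (.cas) and geography (.geo)
text files, plus CSV export of datasets and scan results.

Case file: one line per location/date with a count, ``id count YYYY/MM``.
Geography file: ``id x y``. These plain-text files allow datasets
produced here to be cross-checked against the reference SaTScan
implementation, and real SaTScan inputs to be analyzed with this
package's scan. Months are mapped to a zero-based index relative to a
configurable epoch (default 2007/01, a 48-month study starting January).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .injection import SimulatedDataset
from .scan import ScanResult, SpaceTimeCounts

EPOCH_YEAR = 2007
EPOCH_MONTH = 1


def month_to_date(m: int, epoch_year: int = EPOCH_YEAR, epoch_month: int = EPOCH_MONTH) -> str:
    y, mm = divmod(epoch_month - 1 + int(m), 12)
    return f"{epoch_year + y}/{mm + 1:02d}"


def date_to_month(s: str, epoch_year: int = EPOCH_YEAR, epoch_month: int = EPOCH_MONTH) -> int:
    y, m = s.split("/")
    return (int(y) - epoch_year) * 12 + int(m) - epoch_month


def location_ids(dataset: SimulatedDataset) -> np.ndarray:
    """Location id per record: the areal-unit id at zip/county resolution,
    the case id at address resolution."""
    if dataset.resolution == "address":
        return dataset.records["case_id"].to_numpy()
    return dataset.records[f"{dataset.resolution}_id"].to_numpy()


def write_satscan(dataset: SimulatedDataset, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.cas`` and ``<stem>.geo`` for one dataset."""
    stem = Path(stem)
    rec = dataset.records
    ids = location_ids(dataset)
    cas = stem.with_suffix(".cas")
    geo = stem.with_suffix(".geo")
    grp = (
        pd.DataFrame({"id": ids, "month": rec["month"].to_numpy()})
        .groupby(["id", "month"])
        .size()
        .reset_index(name="count")
    )
    with cas.open("w") as fh:
        for row in grp.itertuples(index=False):
            fh.write(f"{row.id} {row.count} {month_to_date(row.month)}\n")
    locs = pd.DataFrame({"id": ids, "x": rec["x"].to_numpy(), "y": rec["y"].to_numpy()})
    locs = locs.drop_duplicates("id").sort_values("id")
    with geo.open("w") as fh:
        for row in locs.itertuples(index=False):
            fh.write(f"{row.id} {row.x:.6f} {row.y:.6f}\n")
    return cas, geo


def read_satscan(cas_path: str | Path, geo_path: str | Path, n_months: int | None = None) -> SpaceTimeCounts:
    """Build space-time counts from SaTScan case + geography files."""
    geo = pd.read_csv(geo_path, sep=r"\s+", header=None, names=["id", "x", "y"],
                      dtype={"id": str})
    cas = pd.read_csv(cas_path, sep=r"\s+", header=None, names=["id", "count", "date"],
                      dtype={"id": str})
    cas["month"] = cas["date"].map(date_to_month)
    if (cas["count"] < 0).any():
        raise ValueError("negative case count")
    merged = cas.merge(geo, on="id", how="left", validate="many_to_one")
    if merged["x"].isna().any():
        missing = merged.loc[merged["x"].isna(), "id"].unique()
        raise ValueError(f"case locations missing from geography file: {missing[:5]}")
    expanded = merged.loc[merged.index.repeat(merged["count"])]
    from .scan import tabulate  # local import to avoid cycle at module load

    df = pd.DataFrame(
        {
            "x": expanded["x"].to_numpy(float),
            "y": expanded["y"].to_numpy(float),
            "month": expanded["month"].to_numpy(int),
        }
    )
    return tabulate(df, n_months=n_months)


def write_dataset_csv(dataset: SimulatedDataset, path: str | Path) -> None:
    """One-file CSV round trip: truth parameters ride along as columns."""
    rec = dataset.records.copy()
    rec["resolution"] = dataset.resolution
    for k, v in dataset.truth.to_dict().items():
        rec[f"truth_{k}"] = v
    rec.to_csv(path, index=False, float_format="%.17g")  # exact round trip


def read_dataset_csv(path: str | Path) -> SimulatedDataset:
    from .injection import ArtificialCluster

    df = pd.read_csv(path, float_precision="round_trip")
    truth = ArtificialCluster.from_dict(
        {k[len("truth_"):]: df[k].iloc[0] for k in df.columns if k.startswith("truth_")}
    )
    resolution = str(df["resolution"].iloc[0])
    rec = df[[c for c in df.columns if not c.startswith("truth_") and c != "resolution"]]
    return SimulatedDataset(records=rec.reset_index(drop=True), truth=truth,
                            resolution=resolution)


def write_results_csv(result: ScanResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)
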