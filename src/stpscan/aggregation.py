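"""Spatial aggregation: replace case coordinates with areal-unit centroids.

Aggregation models the privacy-motivated practice of releasing case data
at ZIP-code or county resolution: every record keeps its month, flags and
unit assignments, but its coordinates collapse onto the centroid of the
enclosing areal unit. Counts per (unit, month) are preserved exactly;
only geometry changes. The ground-truth cluster is never aggregated.
"""

from __future__ import annotations

from .injection import SimulatedDataset
from .population import ArealUnitSystem

RESOLUTIONS = ("address", "zip", "county")


def aggregate(dataset: SimulatedDataset, units: ArealUnitSystem) -> SimulatedDataset:
    """Return a copy of ``dataset`` at the resolution of ``units``.

    Idempotent: aggregating an already-aggregated dataset with the same
    units maps centroids onto themselves via the stored unit ids.
    """
    col = f"{units.level}_id"
    if col not in dataset.records.columns:
        raise ValueError(f"records lack a {col} assignment")
    ids = dataset.records[col].to_numpy()
    if (ids < 0).any() or (ids >= units.n_units).any():
        raise ValueError(f"record with {col} outside the unit system")
    rec = dataset.records.copy()
    rec["x"] = units.centroids[ids, 0]
    rec["y"] = units.centroids[ids, 1]
    return dataset.copy_with(records=rec, resolution=units.level)


def at_resolution(
    dataset: SimulatedDataset,
    resolution: str,
    zip_units: ArealUnitSystem | None = None,
    county_units: ArealUnitSystem | None = None,
) -> SimulatedDataset:
    """Dispatch helper: identity at address level, centroid replacement
    otherwise."""
    if resolution == "address":
        return dataset
    if resolution == "zip":
        if zip_units is None:
            raise ValueError("zip aggregation requires zip units")
        return aggregate(dataset, zip_units)
    if resolution == "county":
        if county_units is None:
            raise ValueError("county aggregation requires county units")
        return aggregate(dataset, county_units)
    raise ValueError(f"unknown resolution {resolution!r}")
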