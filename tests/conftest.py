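import numpy as np
import pytest

from stpscan import (
    RegionConfig,
    ScanConfig,
    build_study_region,
    inject_dataset,
)
from stpscan.scan import SpaceTimeCounts


@pytest.fixture(scope="session")
def small_region():
    """Fast Tennessee-shaped region with a reduced pool for unit tests."""
    return RegionConfig(
        n_pool=20_000,
        n_blobs=4,
        n_zip_units=80,
        n_county_units=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_region):
    return build_study_region(small_region)


@pytest.fixture(scope="session")
def study_region():
    """Full default study region (122,500-point pool, 617/95 units)."""
    return RegionConfig(seed=7)


@pytest.fixture(scope="session")
def study(study_region):
    return build_study_region(study_region)


@pytest.fixture(scope="session")
def county_dataset(small_study):
    from stpscan import at_resolution

    pop, zips, counties = small_study
    ds = inject_dataset(pop, zips, counties, seed=5)
    return at_resolution(ds, "county", zips, counties)


def make_counts(n_st, coords=None):
    """SpaceTimeCounts from a raw (L, T) count matrix for toy instances."""
    n_st = np.asarray(n_st, dtype=np.int64)
    L = n_st.shape[0]
    if coords is None:
        coords = np.column_stack([np.arange(L, dtype=float), np.zeros(L)])
    case_loc = np.repeat(np.arange(L, dtype=np.int32), n_st.sum(axis=1))
    return SpaceTimeCounts(coords=np.asarray(coords, float), n_st=n_st,
                           case_loc=case_loc)


def quick_scan_config(**kw):
    kw.setdefault("n_replications", 19)
    kw.setdefault("seed", 0)
    return ScanConfig(**kw)
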