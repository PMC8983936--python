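import numpy as np
import pandas as pd
import pytest

import qwa
from qwa import anatomy, synthgen


def make_vessels(rows):
    """Build a vessel table from (site, tree, year, vessel, area, pos[, group]) tuples."""
    cols = ["site_id", "tree_id", "year", "vessel_id", "lumen_area_um2", "rel_position", "group_id"]
    recs = [dict(zip(cols, r + (None,) * (7 - len(r)))) for r in rows]
    return pd.DataFrame(recs)


def make_rings(rows):
    cols = ["site_id", "tree_id", "year", "trw_um", "xylem_area_um2"]
    return pd.DataFrame([dict(zip(cols, r)) for r in rows])


def make_climate(year_start, year_end, rng=None, tmean=10.0, prec=80.0):
    rng = rng or np.random.default_rng(0)
    rows = [
        dict(year=y, month=m,
             tmean_c=tmean + 5 * np.cos(2 * np.pi * (m - 7) / 12) + rng.normal(0, 1),
             prec_mm=max(prec + rng.normal(0, 20), 0.0))
        for y in range(year_start, year_end + 1)
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_config():
    return synthgen.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_data(default_config):
    """One default synthetic stand shared across tests."""
    return synthgen.generate_all(default_config)


@pytest.fixture(scope="session")
def synthetic_traits(synthetic_data):
    vessels, rings, _ = synthetic_data
    scheme = anatomy.SectorScheme(k=10)
    sectorized = anatomy.assign_sectors(vessels, scheme)
    flags = anatomy.filter_sectors(sectorized, rings, scheme)
    return anatomy.sector_traits(sectorized, rings, scheme, flags=flags), flags
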