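import numpy as np
import pandas as pd
import pytest

from riskpm import presets
from riskpm.datatypes import ExposureParams


@pytest.fixture(scope="session")
def params() -> ExposureParams:
    return presets.default_exposure_params()


@pytest.fixture(scope="session")
def toxicity():
    return presets.default_toxicity_table()


@pytest.fixture(scope="session")
def metal_means() -> pd.DataFrame:
    """Campaign zone means for the 7 heavy metals (tidy, ng/m3)."""
    return presets.campaign_zone_table("metals")


@pytest.fixture(scope="session")
def pah_means() -> pd.DataFrame:
    """Campaign zone means for the 14 PAH congeners (tidy, ng/m3)."""
    return presets.campaign_zone_table("pahs")


def make_measurements(values_by_species, zone="North", site="S1",
                      start="2022-02-01", censored=None) -> pd.DataFrame:
    """Build a daily measurement frame from {species: [daily values]}."""
    rows = []
    for sp, values in values_by_species.items():
        dates = pd.date_range(start, periods=len(values), freq="D")
        for k, (d, v) in enumerate(zip(dates, values)):
            c = bool(censored[sp][k]) if censored else False
            rows.append((site, zone, d, sp, float(v), c))
    return pd.DataFrame(rows, columns=["site_id", "zone", "date", "species",
                                       "value_ng_m3", "censored"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
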