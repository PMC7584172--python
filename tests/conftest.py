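import warnings

import numpy as np
import pandas as pd
import pytest

from hwr_community.selection import PipelineConfig, run_pipeline


@pytest.fixture()
def tiny_geography() -> pd.DataFrame:
    """Three counties, one zip spanning two of them (pop 10k vs 50k)."""
    return pd.DataFrame(
        {
            "zip_code": ["10001", "10002", "10003", "10003"],
            "county_fips": ["00001", "00002", "00002", "00003"],
            "county_population": [30000, 50000, 50000, 10000],
            "zip_spans_multiple_counties": [False, False, True, True],
        }
    )


@pytest.fixture(scope="session")
def small_pipeline():
    """One small full pipeline run shared across tests (~3 s)."""
    cfg = PipelineConfig(
        seed=7,
        n_hospitals=60,
        n_counties=60,
        zips_per_county=2,
        n_discharges=9000,
        beta={"Population estimate": 0.6},
        n_trees=80,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
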