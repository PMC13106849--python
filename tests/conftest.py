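import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from honeygeo import synthdata

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_table(pattern_counts, *, year=2020, macro="North", region="North-1",
               lat=45.0, lon=11.0, beekeeper_prefix="BK"):
    """Build a sample table with exact pattern counts (one beekeeper per row)."""
    rows = []
    i = 0
    for pattern, count in pattern_counts.items():
        for _ in range(count):
            rows.append(
                {
                    "sample_id": f"S{i:05d}",
                    "beekeeper_id": f"{beekeeper_prefix}{i:05d}",
                    "year": year,
                    "latitude": lat,
                    "longitude": lon,
                    "region": region,
                    "macro_region": macro,
                    "pattern": pattern,
                }
            )
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture
def emilia_table():
    """576 samples with 20 containing A, 31 containing M, 34 containing A or M.

    A synthetic stand-in reproducing the published regional counts:
    17 samples carry both A and M, 3 carry A without M, 14 carry M
    without A, and the remaining 542 are only-C.
    """
    return make_table({"ACM": 17, "AC": 3, "CM": 14, "C": 542})


@pytest.fixture(scope="session")
def small_survey():
    """A small synthetic survey shared by read-only tests."""
    cfg = synthdata.SimConfig(n_beekeepers=120)
    return synthdata.simulate_dataset(cfg, seed=20260101 % 2**31)


@pytest.fixture(scope="session")
def drift_survey():
    """Paper-faithful synthetic survey: A/M drift in the Central-South only."""
    cfg = synthdata.SimConfig(
        n_beekeepers=400,
        gamma={"A": 0.25, "M": 0.25},
        drift_macros=("Central", "South"),
    )
    return synthdata.simulate_dataset(cfg, seed=7)
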