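import numpy as np
import pandas as pd
import pytest

from medipmark.simulate import CohortSimConfig, TilingSimConfig


@pytest.fixture
def null_tiling_config():
    """A single-chromosome array with no planted promoters (pure noise)."""
    return TilingSimConfig(
        n_chromosomes=1, chrom_length=100_000, n_promoters=0,
        planted_fraction_scc=0.0, planted_fraction_ac=0.0,
        planted_fraction_normal=0.0, fragment_smoothing_bp=0, seed=11,
    )


@pytest.fixture
def small_cohort_config():
    return CohortSimConfig(
        n_per_grade={"Normal": 40, "CIN1": 20, "CIN2": 15, "CIN3/CIS": 20, "SCC": 15},
        failure_rate=0.05, seed=3,
    )


@pytest.fixture
def tiny_probe_table():
    """Ten probes on one chromosome, sorted, with a centered column."""
    starts = np.arange(10) * 100
    df = pd.DataFrame(
        {
            "probe_id": [f"chr1:{s}" for s in starts],
            "chrom": "chr1",
            "start": starts,
            "end": starts + 50,
            "log2_ratio": np.linspace(-0.5, 0.5, 10),
        }
    )
    return df
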