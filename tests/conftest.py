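import numpy as np
import pandas as pd
import pytest

from csrnc import locus_map, synthetic_data as sd


@pytest.fixture(scope="session")
def catalog():
    return locus_map.default_catalog()


@pytest.fixture(scope="session")
def two_archetype_cohort():
    """Well-separated planted design: all-low vs all-high (4 log2 units),
    n = 400, log2 noise SD 1, no zero inflation or dropout."""
    low = np.full(19, 0.5)
    config = sd.SyntheticCohortConfig(
        n_samples=400,
        tissues=[("quiescent", "low_all", 0.5), ("lymphoid", "high_all", 0.5)],
        archetypes={"low_all": low, "high_all": low + 4.0},
        zero_sample_fraction=0.0,
        dropout_fraction=0.0,
        noise_sd=1.0,
        seed=11,
    )
    return sd.generate_cohort(config)
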