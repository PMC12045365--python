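import numpy as np
import pandas as pd
import pytest

from peristroma import (
    DistanceProfile,
    StromaGeometry,
    SyntheticConfig,
    assemble_sample,
    generate_dataset,
)


@pytest.fixture
def small_profile() -> DistanceProfile:
    """Tiny distance profile with 3 of 8 cells marker-positive."""
    d = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 21.0])
    marker = np.array([True, False, True, False, False, True, False, False])
    return DistanceProfile(distances=d, marker=marker, pixel_size=1.0)


@pytest.fixture
def toy_sample():
    """Hand-built 8x8 sample: stroma column at x in [2,3), four tumor cells."""
    stroma = np.zeros((8, 8), dtype=bool)
    stroma[:, 2] = True
    cells = pd.DataFrame(
        {
            "x": [2.5, 3.5, 5.5, 7.5],
            "y": [1.5, 1.5, 4.5, 7.5],
            "cell_class": "tumor",
            "marker": [True, False, True, False],
        }
    )
    return assemble_sample(cells, StromaGeometry(stroma), pixel_size=2.0, sample_id="toy")


@pytest.fixture(scope="session")
def default_sample():
    """One unbiased synthetic sample at the generator's defaults."""
    sample, truth = generate_dataset(SyntheticConfig(seed=42))
    return sample, truth


@pytest.fixture(scope="session")
def biased_sample():
    """One synthetic sample with a strong 10 µm marker bias toward stroma."""
    sample, truth = generate_dataset(SyntheticConfig(seed=42, bias_length=10.0))
    return sample, truth
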