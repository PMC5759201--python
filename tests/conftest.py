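import numpy as np
import pytest

from crosstalkqc import (
    SampleEntry,
    SampleSheet,
    default_combinatorial_plate,
    default_unique_dual_plate,
    sheet_for_samples,
)


@pytest.fixture(scope="session")
def combinatorial_plate():
    return default_combinatorial_plate(seed=5)


@pytest.fixture(scope="session")
def dual_plate():
    """Unique dual-matched plate with 8 wells, 6-nt UMIs."""
    return default_unique_dual_plate(n=8, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def dual_sheet(dual_plate):
    return sheet_for_samples(dual_plate, ["S1", "S2", "S3"])


@pytest.fixture()
def single_sample_sheet(dual_plate):
    return SampleSheet([SampleEntry("S1", dual_plate.sorted_wells()[0])])
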