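import numpy as np
import pytest

from mrfpipe.dictionary import build_dictionary, build_grid, compress
from mrfpipe.signal_model import default_schedule, make_schedule


@pytest.fixture(scope="session")
def schedule500():
    return default_schedule(500)


@pytest.fixture(scope="session")
def schedule120():
    return default_schedule(120)


@pytest.fixture(scope="session")
def default_dictionary(schedule500):
    """Full 27,939-atom dictionary at 500 timepoints, rank-15 compressed."""
    return compress(build_dictionary(build_grid(), schedule500), 15)


@pytest.fixture(scope="session")
def small_dictionary(schedule120):
    """Coarse uncompressed dictionary for cheap unit tests."""
    grid = build_grid([(100, 100, 1500)], [(20, 20, 200)])
    return build_dictionary(grid, schedule120)
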