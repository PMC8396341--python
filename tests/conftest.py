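import numpy as np
import pytest


@pytest.fixture(scope="session")
def hexagon():
    """Six vertices of a regular hexagon with side length 1 (exact coords)."""
    s3 = np.sqrt(3.0) / 2.0
    return np.array(
        [[1.0, 0.0], [0.5, s3], [-0.5, s3], [-1.0, 0.0], [-0.5, -s3], [0.5, -s3]]
    )


@pytest.fixture(scope="session")
def small_cohort():
    from lymphoquant.simtiles import generate_cohort

    return generate_cohort(8, 10, seed=11, width=96, height=96, max_cells=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
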