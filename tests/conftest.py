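import numpy as np
import pytest
from hypothesis import settings

from trapdiv import (
    BandDef,
    MarkerMatrix,
    default_paper_config,
    simulate_matrix,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> MarkerMatrix:
    """4 strains x 5 bands over 2 primer combinations, hand-checkable."""
    bands = [
        BandDef("PA", "b1", 500),
        BandDef("PA", "b2", 300),
        BandDef("PA", "b3", 200),
        BandDef("PB", "b1", 900),
        BandDef("PB", "b2", 150),
    ]
    values = np.array(
        [
            [1, 1, 1, 1, 0],
            [1, 0, 1, 0, 1],
            [1, 1, 0, 1, 1],
            [1, 0, 0, 0, 0],
        ]
    )
    return MarkerMatrix(["w", "x", "y", "z"], bands, values)


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the default 20-strain / 288-band study conditions."""
    return simulate_matrix(default_paper_config(seed=7))
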