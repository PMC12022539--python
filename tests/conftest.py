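import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# make the shared brute-force oracles importable as `oracles`
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def zigzag_pattern():
    """Default 18-row zigzag 10/11 fan, classified 4 fishtail / 2 minor rows."""
    import pavotrain as pt

    lattice = pt.build_lattice("zigzag_10_11", n_rows=18)
    return pt.classify_feathers(pt.expand(lattice), 4, 2)


@pytest.fixture
def parallel_pattern():
    import pavotrain as pt

    lattice = pt.build_lattice("parallel_10_11", n_rows=18)
    return pt.classify_feathers(pt.expand(lattice), 4, 2)
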