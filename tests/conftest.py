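import numpy as np
import pytest

from genclock.simulate import ChromSpec, CohortConfig, GroupSpec


@pytest.fixture
def tiny_config() -> CohortConfig:
    """Two small groups on short chromosomes; fast enough for unit tests."""
    return CohortConfig(
        groups=[
            GroupSpec("WEU", 4, 25.32, 25.32),
            GroupSpec("EAS", 4, 28.0, 28.0),
        ],
        chromosomes=(
            ChromSpec("chr1", 10_000_000),
            ChromSpec("chr2", 10_000_000),
            ChromSpec("chrX", 6_000_000, is_x=True),
            ChromSpec("chrY", 3_000_000, is_y=True),
        ),
        seed=13,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
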