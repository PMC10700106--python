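import numpy as np
import pytest

from phagemosaic.homology import find_homology_regions
from phagemosaic.pipeline import analyze_recombinant
from phagemosaic.simulate import RegionSpec, SimConfig, compact_config, simulate_trio


def hifi_config(seed: int = 0) -> SimConfig:
    """Compact config with both regions at high identity (>=97%), the regime
    for clean flipflop calling; site density ~1 per 25-35 bp."""
    return SimConfig(
        seed=seed,
        len_a=15000,
        len_b=16500,
        regions=(
            RegionSpec(a_start=3001, b_start=3501, length=1200, identity=97.0),
            RegionSpec(a_start=9001, b_start=8101, length=1200, identity=98.0),
        ),
    )


@pytest.fixture(scope="session")
def full_trio():
    """Study-scale simulated parents + one double-crossover recombinant."""
    return simulate_trio(SimConfig(seed=1))


@pytest.fixture(scope="session")
def full_analysis(full_trio):
    parent_a, parent_b, rec, truth = full_trio
    regions = find_homology_regions(parent_a, parent_b)
    analysis = analyze_recombinant(parent_a, parent_b, regions, rec)
    return regions, analysis, truth


@pytest.fixture(scope="session")
def compact_trio():
    return simulate_trio(compact_config(seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
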