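import numpy as np
import pandas as pd
import pytest

from crosspred.io_qc import GeneticMap, GenotypeMatrix
from crosspred.synthetic_data import make_breeding_scenario, small_config


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_marker_map():
    """Two markers 20 cM apart on one chromosome."""
    return GeneticMap(
        pd.DataFrame(
            {"marker_id": ["a", "b"], "chromosome": ["1", "1"], "position_cM": [0.0, 20.0]}
        )
    )


@pytest.fixture
def five_marker_map():
    return GeneticMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(5)],
                "chromosome": ["1"] * 5,
                "position_cM": [0.0, 25.0, 50.0, 75.0, 100.0],
            }
        )
    )


def random_genotypes(n_lines, n_markers, seed=0, with_missing=False):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=(n_lines, n_markers)).astype(np.int8)
    if with_missing:
        mask = rng.random(calls.shape) < 0.1
        calls[mask] = -1
    return GenotypeMatrix(
        [f"L{i:03d}" for i in range(n_lines)],
        [f"M{j:04d}" for j in range(n_markers)],
        calls,
    )


@pytest.fixture(scope="session")
def tiny_scenario():
    """A small but complete breeding scenario shared by read-only tests."""
    return make_breeding_scenario(small_config(seed=11))
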