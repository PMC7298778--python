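import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from caskit import SimConfig, generate_bitscore_dataset
from caskit.subfamilies import build_profile_from_cluster


@pytest.fixture(scope="session")
def peaked_model():
    """Profile built from many identical copies of ACDE (pseudocount 0.01)."""
    return build_profile_from_cluster(["ACDE"] * 20, pseudocount=0.01,
                                      name="cas9__cluster1", family="cas9")


@pytest.fixture(scope="session")
def separable_matrix():
    """Default planted dataset: 3 subtypes x 100, one signature family each."""
    matrix, truth = generate_bitscore_dataset(SimConfig(seed=11))
    return matrix, truth


@pytest.fixture(scope="session")
def module_matrix():
    """Planted linear-dependency dataset for regression/rule tests."""
    from caskit.simulate import default_module_config

    cfg = default_module_config(seed=23)
    matrix, truth = generate_bitscore_dataset(cfg)
    return matrix, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
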