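from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from estindel import PipelineConfig, SimConfig, discover, simulate_tetraploid_pair


@pytest.fixture(scope="session")
def sim200():
    """The default study scenario: 200 genes, seed 42."""
    return simulate_tetraploid_pair(SimConfig(n_genes=200, seed=42))


@pytest.fixture(scope="session")
def disc200(sim200):
    """Full discovery run on the default scenario."""
    return discover(sim200.query, sim200.target, PipelineConfig(seed=42))


@pytest.fixture(scope="session")
def sim_small():
    """A fast scenario for pipeline-level smoke tests."""
    return simulate_tetraploid_pair(SimConfig(n_genes=25, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
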