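import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from msm.calling import BranchSamplePair
from msm.countio import FilterConfig
from msm.depth import depth_ranges
from msm.synthetic import (
    MixtureModel,
    NoiseModel,
    SyntheticGenome,
    TISSUES,
    simulate_counts,
    simulate_truth,
)
from msm.topology import TreeTopology


@pytest.fixture(scope="session")
def topology() -> TreeTopology:
    return TreeTopology.default()


@pytest.fixture(scope="session")
def genome() -> SyntheticGenome:
    return SyntheticGenome(seed=11)


@pytest.fixture(scope="session")
def cfg() -> FilterConfig:
    return FilterConfig()


@pytest.fixture(scope="session")
def small_simulation(topology, genome, cfg):
    """One full simulated dataset shared by read-only tests."""
    truth = simulate_truth(topology, seed=11, genome=genome)
    noise = NoiseModel(seed=11)
    mixture = MixtureModel()
    samples = [(b, t) for b in topology.tips for t in TISSUES]
    tables = simulate_counts(truth, mixture, noise, samples, n_background=4000)
    ranges = depth_ranges(tables)
    pairs = {
        b: BranchSamplePair(
            b, tables[f"{b}.L1-fruit"], tables[f"{b}.L2-fruit"], tables[f"{b}.leaf"]
        )
        for b in topology.tips
    }
    return dict(
        truth=truth, tables=tables, ranges=ranges, pairs=pairs,
        mixture=mixture, noise=noise,
    )
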