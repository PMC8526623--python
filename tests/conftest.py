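import numpy as np
import pytest

from polkinetics.simulate import SimConfig, default_ground_truth, \
    make_toy_annotation
from polkinetics.tracks import SignalTrack


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_genes=8, gene_length_range=(40_000, 60_000))


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    return make_toy_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return default_ground_truth(small_cfg)


@pytest.fixture()
def tiny_track():
    """1 kb single-chromosome stranded track, initially zero."""
    return SignalTrack({"chr1": 1000}, stranded=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
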