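import warnings

import numpy as np
import pytest

from erpstats.montage import (
    RegionOverlapWarning,
    build_adjacency,
    build_default_layout,
    build_region_map,
)
from erpstats.synth import NoiseSpec, StudyDesign, simulate_noise_epochs


@pytest.fixture(scope="session")
def layout61():
    return build_default_layout()


@pytest.fixture(scope="session")
def region_map():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RegionOverlapWarning)
        return build_region_map()


@pytest.fixture(scope="session")
def adjacency61(layout61):
    return build_adjacency(layout61, scale=1.5)


@pytest.fixture(scope="session")
def layout16(layout61):
    return layout61.subset(list(range(1, 17)))


@pytest.fixture(scope="session")
def adjacency16(layout16):
    return build_adjacency(layout16, scale=1.5)


@pytest.fixture(scope="session")
def small_epochs(layout16):
    """4 subjects x 3 conditions x 6 trials x 16 electrodes x 0.8 s @ 100 Hz."""
    design = StudyDesign(
        n_subjects=4,
        trials_per_condition=6,
        sfreq=100.0,
        epoch_window=(-0.2, 0.6),
        conditions=("a", "b", "c"),
    )
    return simulate_noise_epochs(design, NoiseSpec(sd_broadband=12.0), layout16, seed=321)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
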