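import numpy as np
import pytest

import sphericell as sc


@pytest.fixture(scope="session")
def metaphase_phantom():
    """Noiseless metaphase phantom with DAPI + spindle + centrosome channels."""
    cfg = sc.PhantomConfig(
        phase=sc.METAPHASE,
        stack_shape=(48, 64, 64),
        voxel_spacing=(0.5, 0.5, 0.5),
        axis_direction=(1.0, 0.0, 0.0),
        chromatin_half_axes=(7.0, 6.0, 3.5),
        channel_patterns=[
            sc.ChannelPattern("DAPI", "chromatin", amplitude=100.0),
            sc.ChannelPattern("b-tubulin", "spindle", amplitude=80.0),
            sc.ChannelPattern("g-tubulin", "centrosome", amplitude=120.0),
            sc.ChannelPattern("uniform", "uniform", amplitude=30.0),
        ],
        background=10.0,
    )
    stack, truth = sc.make_phantom(cfg, seed=1)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def segregation_phantom():
    cfg = sc.PhantomConfig(
        phase=sc.SEGREGATION,
        stack_shape=(48, 64, 64),
        voxel_spacing=(0.5, 0.5, 0.5),
        axis_direction=(1.0, 0.0, 0.0),
        chromatin_half_axes=(4.0, 3.5, 3.0),
        centroid_distance=9.0,
        channel_patterns=[sc.ChannelPattern("DAPI", "chromatin", amplitude=100.0)],
        background=10.0,
    )
    stack, truth = sc.make_phantom(cfg, seed=2)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def small_truth():
    """Ground truth for a 3-species affinity model with one planted pair."""
    return sc.make_ground_truth(["DAPI", "A", "B"], [(1, 2)], seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    totals = sc.simulate_cell_totals(small_truth, 40, seed=12)
    return sc.simulate_roi_dataset(small_truth, totals, with_noise=True, seed=13)


@pytest.fixture(scope="session")
def template_map():
    """Intensity template (2 channels x 6 x 3) for statistics fixtures."""
    rng = np.random.default_rng(3)
    return np.exp(rng.normal(np.log(50.0), 0.3, (2, 6, 3)))
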