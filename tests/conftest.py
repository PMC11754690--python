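import numpy as np
import pytest

from holoflow import (
    FlowScene,
    OpticalConfig,
    default_phantom_sampler,
    simulate_video,
)


@pytest.fixture(scope="session")
def default_scene():
    """One simulated default-sized scene shared by read-only tests."""
    scene = FlowScene(seed=7)
    optics = OpticalConfig().snap_carrier(scene.frame_shape)
    video, truth = simulate_video(scene, default_phantom_sampler(), optics)
    return {"scene": scene, "optics": optics, "video": video, "truth": truth}


@pytest.fixture(scope="session")
def sweep_results():
    """The full desk-scale multi-view experiment (the expensive fixture:
    several minutes; shared by the acceptance criteria 5 and 6 tests)."""
    from holoflow.experiments import multiview_experiment

    return multiview_experiment()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
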