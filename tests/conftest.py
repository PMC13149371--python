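import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deptrack.experiments import (
    ExperimentConfig,
    make_experiment,
    tracking_schedule,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_benchmark():
    """A 12-cell short-schedule experiment with simulated ground truth."""
    exp = make_experiment(ExperimentConfig(n_cells=12, seed=5), schedule=tracking_schedule())
    tracks = exp.run()
    return exp, tracks


@pytest.fixture(scope="session")
def rendered_first_frame(small_benchmark):
    from deptrack.simulate import render_frame

    exp, tracks = small_benchmark
    return render_frame(exp.layout, tracks, 0, seed=5)


@pytest.fixture(scope="session")
def fov_mask(rendered_first_frame):
    from deptrack.fovmask import make_fov_mask

    return make_fov_mask(rendered_first_frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
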