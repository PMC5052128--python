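import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import slicseg

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Two-view phantom small enough for repeated pipeline tests."""
    spec = slicseg.PhantomSpec(
        grid_shape=(80, 80, 20),
        spacing=((1.0, 1.0, 4.0), (1.0, 1.0, 5.0)),
        seed=7,
    )
    return slicseg.generate_study(spec, 2)


@pytest.fixture(scope="session")
def single_view(small_study):
    """(volume, truth, start scribbles) for the first view."""
    volume = small_study.volumes[0]
    truth = small_study.truths[0]
    start = int(np.argmax(truth.data.sum(axis=(1, 2))))
    scribbles = slicseg.auto_scribbles(truth, start, fg_len_mm=40,
                                       bg_len_mm=100, seed=3)
    return volume, truth, scribbles


@pytest.fixture(scope="session")
def propagated(single_view):
    """Full-variant propagation result for the first view (computed once)."""
    volume, _, scribbles = single_view
    return slicseg.propagate(volume, scribbles, slicseg.SegConfig())
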