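import numpy as np
import pytest

from spindlemech.config import RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def circle_arc(radius, angle_span, n=200, center=(0.0, 0.0), start_angle=0.0):
    """Sampled circular arc; analytic length = radius * angle_span."""
    th = np.linspace(start_angle, start_angle + angle_span, n)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


@pytest.fixture
def arc_factory():
    return circle_arc
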