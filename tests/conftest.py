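import numpy as np
import pytest

import glvflux as g


@pytest.fixture(scope="session")
def wolf_rabbit_model():
    return g.WOLF_RABBIT_MODEL


@pytest.fixture(scope="session")
def wolf_rabbit_orbit(wolf_rabbit_model):
    """Displaced predator-prey orbit spanning a bit over three cycles."""
    return g.integrate_glv(wolf_rabbit_model, [1500.0, 60.0], 110.0, dt_out=0.01)


@pytest.fixture(scope="session")
def wolf_rabbit_short(wolf_rabbit_model):
    """Shorter, coarser orbit for quadratic-cost density-measure sweeps."""
    return g.integrate_glv(wolf_rabbit_model, [1500.0, 60.0], 40.0, dt_out=0.02)


@pytest.fixture(scope="session")
def logistic_trajectory():
    """Single-species logistic growth toward carrying capacity 1."""
    model = g.GLVModel(r=[1.0], A=[[-1.0]])
    return g.integrate_glv(model, [0.5], 8.0, dt_out=0.004)
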