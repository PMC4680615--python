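import numpy as np
import pytest

from veilflow.spheroid import CellGeometry
from veilflow.synthetic import ChamberConfig, simulate_chamber
from veilflow.tether import DynamicsParams
from veilflow.wallflow import FluidProperties


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def thiovulum_params():
    return DynamicsParams(
        geometry=CellGeometry.from_aspect_ratio(1.3, 4.25), force_pn=40.0
    )


@pytest.fixture(scope="session")
def uronemella_params():
    return DynamicsParams(
        geometry=CellGeometry.from_aspect_ratio(2.0, 12.5), force_pn=50.0
    )


@pytest.fixture(scope="session")
def chamber_states():
    """Default chamber run at the ciliate's preferred concentration.

    Session-scoped: the aerotactic-band simulation is by far the most
    expensive fixture and several measurement tests read from it.
    """
    config = ChamberConfig(preferred_pct=7.0, seed=1)
    return simulate_chamber(config)
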