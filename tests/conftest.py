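import numpy as np
import pytest
from hypothesis import settings

from hrscreen.plates import PlateReadout, default_control_layout

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def layout():
    return default_control_layout("p1")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_readout(values_by_label, layout=None, replicate_id=1):
    """Build a PlateReadout from {'A1': value} style dicts."""
    from hrscreen.plates import parse_well_address

    lay = layout or default_control_layout("p1")
    values = {parse_well_address(k): v for k, v in values_by_label.items()}
    return PlateReadout(layout=lay, values=values, replicate_id=replicate_id)


@pytest.fixture
def readout_factory():
    return make_readout
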