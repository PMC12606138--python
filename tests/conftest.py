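import numpy as np
import pytest

from placefields.config import TrackConfig
from placefields.signals import running_mask
from placefields.synth import simulate_trajectory

#: default zone layout: two adjacent 33 cm (12-bin) zones, bin-aligned
OPTO = (26.0, 59.0)
CONTROL = (59.0, 92.0)


@pytest.fixture(scope="session")
def cfg():
    return TrackConfig(opto_zone=OPTO, control_zone=CONTROL)


@pytest.fixture(scope="session")
def traj20(cfg):
    """A 20-lap session at typical running speed."""
    return simulate_trajectory(cfg, n_laps=20, mean_speed=15.0, pause_s=1.0, seed=1)


@pytest.fixture(scope="session")
def mask20(traj20):
    return running_mask(traj20.v, traj20)
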