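"""Shared fixtures: all test data is generated programmatically by the
synthetic-retina simulator (no stored fixtures)."""
import numpy as np
import pytest

from premotion import RetinaGeometry, RunConfig
from premotion.simulate import (FullFieldProtocol, GratingProtocol,
                                MovingBarProtocol, WhiteNoiseProtocol,
                                make_population, simulate_session)


@pytest.fixture(scope="session")
def geom():
    return RetinaGeometry.rectangle(1600.0, 1600.0)


@pytest.fixture(scope="session")
def bar_recording(geom):
    """16 cells (8 with an activation zone at a random angle, 8 symmetric)
    under the standard 900 um / 600 um/s moving-bar protocol."""
    cells = make_population(16, seed=11, geometry=geom, frac_az=0.5,
                            az_angle="random")
    return simulate_session(cells, [MovingBarProtocol()], geom, seed=12)


@pytest.fixture(scope="session")
def battery_recording(geom):
    """Small full stimulus battery (white noise, full field, gratings,
    moving bars) for screen / IO tests."""
    cells = make_population(6, seed=21, geometry=geom, frac_az=0.5,
                            az_angle="random")
    protos = [WhiteNoiseProtocol(duration=150.0),
              FullFieldProtocol(),
              GratingProtocol(n_repeats=3),
              MovingBarProtocol()]
    return simulate_session(cells, protos, geom, seed=22)


@pytest.fixture(scope="session")
def default_cfg():
    return RunConfig()
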