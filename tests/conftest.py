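"""Shared fixtures: small, fast geometries reused across test modules."""

import numpy as np
import pytest

from dtraf import SynthConfig, gen_geometry


@pytest.fixture(scope="session")
def small_config():
    """A compact single-dendrite field that renders in milliseconds."""
    return SynthConfig(
        image_shape=(60, 700),
        soma_center_um=(3.5, 3.0),
        soma_radius_um=2.5,
        dendrite_length_um=60.0,
        spine_spacing_um=4.0,
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    """(geometry, label mask) for the small config."""
    return gen_geometry(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
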