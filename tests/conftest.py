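"""Shared fixtures: phantom meshes and solved fields are built once per session."""

import numpy as np
import pytest

from vestfem.phantom import PhantomConfig, build_phantom, place_electrodes


@pytest.fixture(scope="session")
def coarse_phantom():
    """Desk-scale phantom (~20k tets) used by solver and recruitment tests."""
    return build_phantom(PhantomConfig(resolution=2.0, seed=0))


@pytest.fixture(scope="session")
def coarse_phantom_bipolar():
    return build_phantom(
        PhantomConfig(resolution=2.0, electrode_mode="bipolar", seed=0)
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Default-resolution phantom (~1e5 tets)."""
    return build_phantom(PhantomConfig(resolution=1.0, seed=0))


@pytest.fixture(scope="session")
def coarse_electrodes(coarse_phantom):
    return place_electrodes(coarse_phantom, "monopolar")


@pytest.fixture(scope="session")
def coarse_electrodes_bipolar(coarse_phantom_bipolar):
    return place_electrodes(coarse_phantom_bipolar, "bipolar")
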