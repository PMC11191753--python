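import numpy as np
import pytest

import spinefem as sf


@pytest.fixture(scope="session")
def default_geometry():
    return sf.build_segment()


@pytest.fixture(scope="session")
def default_mesh(default_geometry):
    return sf.generate_mesh(default_geometry, sf.MeshSettings())


@pytest.fixture(scope="session")
def coarse_settings():
    """Coarse density for fast solve-level tests."""
    return sf.MeshSettings(target_edge_solid=8.0, target_edge_cartilage=2.0,
                           element_order=2)


@pytest.fixture(scope="session")
def coarse_mesh(default_geometry, coarse_settings):
    return sf.generate_mesh(default_geometry, coarse_settings)
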