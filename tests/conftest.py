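import numpy as np
import pytest

from chargebem import (
    SphereSpec,
    make_figure8,
    make_icosphere,
    make_sphere_model,
    transform_coil,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def icosphere_320():
    """Unit icosphere with 320 facets (2 subdivisions)."""
    return make_icosphere(1.0, 2)


@pytest.fixture(scope="session")
def single_sphere_small():
    """Single conducting sphere in air, 320 facets, with interior probes."""
    spec = SphereSpec([0.09], [0.33], subdivisions=2)
    return make_sphere_model(spec, n_probes=200)


@pytest.fixture(scope="session")
def three_layer_small():
    """Three-layer sphere model at coarse resolution (320 facets/surface)."""
    spec = SphereSpec([0.09, 0.085, 0.08], [0.33, 0.01, 0.33], subdivisions=2)
    return make_sphere_model(spec, n_probes=300)


@pytest.fixture(scope="session")
def fig8_above_sphere():
    """Figure-8 coil 5 mm above the r=0.09 m sphere's north pole."""
    return transform_coil(make_figure8(), np.eye(3), [0.0, 0.0, 0.095])
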