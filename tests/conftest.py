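import numpy as np
import pytest

from eegbem.forward import BemSystem
from eegbem.geometry import (LayeredHeadModel, make_icosphere,
                             make_layered_sphere_model, place_electrodes)


@pytest.fixture(scope="session")
def sphere_s2():
    """Single 9 cm icosphere at subdivision 2 (320 facets)."""
    return make_icosphere(0.09, 2)


@pytest.fixture(scope="session")
def model3_s2():
    """Coarse three-layer SimNIBS3 sphere model (subdivision 2)."""
    return make_layered_sphere_model([0.092, 0.086, 0.080], preset="SimNIBS3",
                                     subdivisions=2)


@pytest.fixture(scope="session")
def model3_s3():
    """Three-layer SimNIBS3 sphere model at subdivision 3 (1280/layer)."""
    return make_layered_sphere_model([0.092, 0.086, 0.080], preset="SimNIBS3",
                                     subdivisions=3)


@pytest.fixture(scope="session")
def homogeneous_model_s3():
    """Homogeneous 9 cm sphere (single layer, subdivision 3)."""
    return LayeredHeadModel([make_icosphere(0.09, 3)], [0.33])


@pytest.fixture(scope="session")
def electrodes64(homogeneous_model_s3):
    return place_electrodes(homogeneous_model_s3.surfaces[0], 64)


@pytest.fixture(scope="session")
def electrodes256_s3(model3_s3):
    return place_electrodes(model3_s3.surfaces[0], 256)


@pytest.fixture(scope="session")
def system3_s3(model3_s3):
    return BemSystem.from_model(model3_s3)


def average_reference(v):
    v = np.asarray(v, dtype=float)
    return v - v.mean()
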