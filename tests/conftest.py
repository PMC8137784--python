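import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petlvef import (
    AcquisitionConfig,
    DoseModel,
    PhantomSpec,
    RvSpec,
    build_phantom_pair,
    default_phantom_spec,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# isotropic contraction factor taking the ED cavity to the ES cavity volume
CONTRACTION = (62.0 / 110.0) ** (1.0 / 3.0)


def make_small_spec(with_rv: bool = True) -> PhantomSpec:
    """A quick-to-voxelize phantom for unit tests: ~28 cm^3 ED cavity on an
    (80, 64, 64) grid of 2 mm voxels, same contraction as the study pair."""
    ed = (30.0, 15.0, 15.0)
    es = tuple(s * CONTRACTION for s in ed)
    rv = None
    if with_rv:
        rv_ed = (24.0, 12.0, 10.0)
        rv = RvSpec(
            ed_semi_axes_mm=rv_ed,
            es_semi_axes_mm=tuple(s * CONTRACTION for s in rv_ed),
            center_mm=(80.0, 64.0, 101.0),
        )
    return PhantomSpec(
        grid_shape=(80, 64, 64),
        voxel_size_mm=(2.0, 2.0, 2.0),
        lv_ed_semi_axes_mm=ed,
        lv_es_semi_axes_mm=es,
        lv_center_mm=(80.0, 64.0, 64.0),
        wall_thickness_mm=8.0,
        rv_spec=rv,
    )


@pytest.fixture(scope="session")
def small_spec():
    return make_small_spec()


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return build_phantom_pair(small_spec)


@pytest.fixture(scope="session")
def full_pair():
    """The study phantom: 220^3 at 1.65 mm, cavities calibrated to 110/62 cm^3."""
    return build_phantom_pair(default_phantom_spec())


@pytest.fixture()
def dose():
    return DoseModel(injected_activity_MBq=140.0)


@pytest.fixture()
def noiseless_acq():
    return AcquisitionConfig(poisson_noise=False, psf_fwhm_mm=0.0)
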