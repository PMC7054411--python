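import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nanoct as nc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom48():
    """48³ soft-tissue fixture phantom at 540 nm voxels."""
    return nc.generate_phantom(nc.default_phantom_spec(48, 540.0, seed=1))


@pytest.fixture(scope="session")
def geom48():
    """Cone-beam geometry matched to the 48³ phantom, zero axis offset."""
    return nc.ConeBeamGeometry.from_effective_pixel(
        540.0, det_n_u=72, det_n_v=72, sod_mm=0.6
    )


@pytest.fixture(scope="session")
def clean_stack48(phantom48, geom48):
    """Noise-free, drift-free 90-view scan of the 48³ phantom."""
    return nc.project_cone_beam(phantom48, geom48, nc.make_angular_grid(90, 360.0))


@pytest.fixture(scope="session")
def noisy_stack48(clean_stack48):
    """Same scan with Poisson noise at i0 = 10⁴ and vignetted flats."""
    return nc.apply_noise_and_flats(clean_stack48, i0=1.0e4, seed=11)


@pytest.fixture(scope="session")
def align_cfg():
    return nc.AlignConfig(
        coarse_factor=2, search_halfwidth_px=5.0, tol_px=0.1, eval_slab=6, seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
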