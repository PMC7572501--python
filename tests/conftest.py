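import numpy as np
import pytest

from lspost.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_plane_16(rng):
    return rng.integers(0, 65536, size=(32, 32)).astype(np.uint16)


@pytest.fixture(scope="session")
def striped_phantom_pair():
    """Small striped phantom plus its stripe-free twin (same seed, no occluders)."""
    kwargs = dict(
        shape=(4, 128, 128),
        stripe_angle_deg=25.0,
        shadow_attenuation=0.5,
        shadow_width=1.5,
        n_vessels=2,
        vessel_radius=(1.5, 2.5),
        vessel_intensity=14000.0,
        n_nuclei=8,
        nucleus_intensity=4000.0,
        noise_sigma=50.0,
        seed=11,
    )
    striped, truth = generate_phantom(PhantomSpec(occluders_per_plane=15, **kwargs))
    twin, _ = generate_phantom(PhantomSpec(occluders_per_plane=0, **kwargs))
    return striped, twin, truth
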