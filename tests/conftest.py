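import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ioertdose.applicator import ApplicatorSpec
from ioertdose.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def still_phantom():
    """Noiseless, motion-free default phantom (14.5 mm target gap)."""
    cfg = PhantomConfig(seed=1, noise_sigma_hu=0.0,
                        motion_rotation_deg=(0, 0, 0),
                        motion_translation_mm=(0, 0, 0))
    return cfg, generate_phantom(cfg)


@pytest.fixture(scope="session")
def moved_phantom():
    """Default phantom with rigid motion and HU noise (study-like conditions)."""
    cfg = PhantomConfig(seed=3)
    return cfg, generate_phantom(cfg)


@pytest.fixture(scope="session")
def tilted_phantom():
    """Noiseless phantom with a tilted 30-degree-bevel applicator."""
    cfg = PhantomConfig(seed=5, noise_sigma_hu=0.0,
                        motion_rotation_deg=(0, 0, 0),
                        motion_translation_mm=(0, 0, 0),
                        applicator_tilt_deg=(6.0, -4.0),
                        applicator_roll_deg=300.0,
                        spec=ApplicatorSpec(diameter_cm=7.0, bevel_angle_deg=30.0))
    return cfg, generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def smooth_dose_pair(shape=(40, 40, 40), spacing=(1.5, 1.5, 1.5), seed=0,
                     scale=5.0, perturb=0.0):
    """Seeded smooth 3D dose-like fields in [0, 100] for gamma tests."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.normal(0, 1, shape), scale)
    f -= f.min()
    f *= 100.0 / f.max()
    g = f.copy()
    if perturb:
        g = np.clip(f * (1.0 + perturb) + rng.normal(0, perturb * 20, shape), 0, None)
    from ioertdose.dose import DoseGrid

    return (DoseGrid(f, spacing, (0.0, 0.0, 0.0)),
            DoseGrid(g, spacing, (0.0, 0.0, 0.0)))
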