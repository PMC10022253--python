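"""Shared fixtures: baseline landmarks, phantoms, and simulated cohorts."""

import numpy as np
import pytest

from glenovol import ScapularLandmarks, build_frame
from glenovol.simulate import PhantomSpec, make_phantom


@pytest.fixture
def baseline_landmarks():
    """Axis-aligned scapula: plane y=0, medial border along z, glenoid lateral."""
    return ScapularLandmarks(angulus_inferior=[0.0, 0.0, 0.0],
                             trigonum_scapulae=[0.0, 0.0, 100.0],
                             glenoid_center=[60.0, 0.0, 80.0], side="right")


@pytest.fixture
def baseline_frame(baseline_landmarks):
    return build_frame(baseline_landmarks)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noiseless 20 mm solid sphere at 1 mm isotropic spacing."""
    return make_phantom(PhantomSpec(shape="solid_sphere", radius_mm=20.0,
                                    spacing_mm=1.0, noise_sd=0.0), rng=0)


@pytest.fixture(scope="session")
def noisy_sphere_phantom():
    """Same sphere with the generator's standard acquisition noise."""
    return make_phantom(PhantomSpec(shape="solid_sphere", radius_mm=20.0,
                                    spacing_mm=1.0, noise_sd=20.0), rng=1)


@pytest.fixture(scope="session")
def shell_phantom():
    """Centered spherical shell R=30, r=25 (analytic total 47.66 mL)."""
    return make_phantom(PhantomSpec(shape="spherical_shell", radius_mm=30.0,
                                    inner_radius_mm=25.0, grid_shape=(70, 70, 70),
                                    spacing_mm=1.0, noise_sd=0.0), rng=0)


def random_rotation(rng, max_angle_rad):
    """Uniform-axis rotation with angle < max_angle_rad (keeps anatomy plausible)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.1, max_angle_rad)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
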