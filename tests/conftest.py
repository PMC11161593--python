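"""Shared fixtures; expensive PSF computations are session-scoped."""

import numpy as np
import pytest

from phaseplate import (
    OpticalConfig,
    PhaseMask,
    compute_probe_set,
    phase_to_displacement,
    standard_pattern_2d,
    standard_pattern_3d,
)


@pytest.fixture(scope="session")
def config() -> OpticalConfig:
    """The reference optical system: NA 1.35, n 1.406, 635 nm, flat 7 mm beam."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def lateral_slope(config):
    """Fitted minimum displacement per degree of EOM phase, bisected-x mask."""
    return phase_to_displacement(config, PhaseMask.bisected("x"))


@pytest.fixture(scope="session")
def axial_slope(config):
    return phase_to_displacement(config, PhaseMask.tophat())


@pytest.fixture(scope="session")
def probe_set_2d_fine(config):
    """Bilobed x+y probe set on a fine (0.5 nm) focal-plane grid, b = 0.5%."""
    fine = np.arange(-20.0, 20.25, 0.5)
    return compute_probe_set(
        config, standard_pattern_2d(50.0), b=0.005,
        x=fine, y=fine, z=np.array([0.0]),
    )


@pytest.fixture(scope="session")
def sigma_2d(config):
    from phaseplate import center_sigma

    return center_sigma(config, standard_pattern_2d(50.0), b=0.005)


@pytest.fixture(scope="session")
def sigma_3d(config):
    from phaseplate import center_sigma

    return center_sigma(config, standard_pattern_3d(50.0, 150.0), b=0.005)
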