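"""Shared fixtures.

Session scope is used for anything that costs more than ~1 s (particle
calibration, full-image simulations, the resolution experiment) so the suite
stays fast while tests share one canonical operating point: 74 mm zoomed FOV,
5.8 mT drive, 1.13 T/m gradient, 6 mT third-harmonic kernel.
"""

import numpy as np
import pytest

from mpisim import (ScannerConfig, SPIONModel, bin_to_sinogram,
                    make_line_pair, make_point_source, simulate_image,
                    run_resolution_experiment)
from mpisim.preprocess import preprocess_sinogram


@pytest.fixture(scope="session")
def config74():
    """Zoomed 74 mm FOV operating point used for the resolution phantoms."""
    return ScannerConfig.with_fov(74.0)


@pytest.fixture(scope="session")
def spion(config74):
    """Synomag-D-like particle calibrated to the 6 mT kernel at 5.8 mT drive."""
    return SPIONModel.from_kernel_fwhm(6.0, config74.drive_amplitude)


@pytest.fixture(scope="session")
def linepair_sinogram(config74, spion):
    """Preprocessed noiseless 7 mm line-pair sinogram (shared, read-only)."""
    phantom = make_line_pair(7.0)
    readouts = simulate_image(phantom, config74, spion, seed=0)
    return preprocess_sinogram(bin_to_sinogram(readouts, config74),
                               harmonics=3)


@pytest.fixture(scope="session")
def point_sinogram(config74, spion):
    """Preprocessed noiseless off-center point-source sinogram."""
    phantom = make_point_source(20.0, 6.0, pixel_pitch=0.5,
                                center=(10.0, -5.0))
    readouts = simulate_image(phantom, config74, spion, seed=0)
    return preprocess_sinogram(bin_to_sinogram(readouts, config74),
                               harmonics=3)


@pytest.fixture(scope="session")
def resolution_result():
    """The full noiseless capillary-pair experiment, both reconstructions."""
    return run_resolution_experiment()
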