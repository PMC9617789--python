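"""Shared fixtures.

Expensive pipeline fixtures are session-scoped; everything is generated
programmatically (no stored binary test data).
"""

from __future__ import annotations

import numpy as np
import pytest

import siimrecon as sr
from siimrecon.calibration import espirit_maps, make_intensity_map, ssg_calibrate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sms3_protocol():
    """The full acquisition geometry at phantom scale: SMS=3, R=4, pf=6/8."""
    return sr.AcquisitionProtocol(
        matrix_size=(96, 96), n_coils=20, sms_factor=3, n_groups=1, n_frames=12
    )


@pytest.fixture(scope="session")
def sms3_phantom(sms3_protocol):
    cfg = sr.PhantomConfig(
        matrix_size=(96, 96), n_slices=3, n_frames=12, n_coils=20, seed=7,
        coil_width_frac=0.35,
    )
    return sr.generate_phantom(cfg)


@pytest.fixture(scope="session")
def sms3_acquisition(sms3_phantom, sms3_protocol):
    kspace, calib = sr.simulate_acquisition(sms3_phantom, sms3_protocol, seed=7)
    caipi = sr.make_caipi_schedule(sms3_protocol, kspace.pattern_ref)
    return kspace, calib, kspace.pattern_ref, caipi


@pytest.fixture(scope="session")
def sms3_kernels(sms3_acquisition, sms3_protocol):
    _, calib, pattern, _ = sms3_acquisition
    return ssg_calibrate(calib, sms3_protocol, pattern=pattern)


@pytest.fixture(scope="session")
def sms3_maps(sms3_acquisition, sms3_protocol):
    _, calib, _, _ = sms3_acquisition
    return espirit_maps(
        calib, sms3_protocol.matrix_size, calib_size=sms3_protocol.calib_size
    )


@pytest.fixture(scope="session")
def sms3_intensity(sms3_acquisition, sms3_kernels, sms3_maps, sms3_protocol):
    kspace, _, pattern, _ = sms3_acquisition
    return make_intensity_map(
        kspace.data, sms3_kernels, sms3_maps, pattern, sms3_protocol.calib_size
    )


@pytest.fixture(scope="session")
def wellposed_setup():
    """A well-conditioned instance for exact-identity tests: SMS=2, R=2,
    no partial Fourier, 8 coils."""
    protocol = sr.AcquisitionProtocol(
        matrix_size=(48, 48),
        n_coils=8,
        sms_factor=2,
        n_groups=1,
        n_frames=4,
        in_plane_R=2,
        partial_fourier=1,
        fov_shift_fraction="1/2",
    )
    phantom = sr.generate_phantom(
        sr.PhantomConfig(matrix_size=(48, 48), n_slices=2, n_frames=4, n_coils=8)
    )
    kspace, calib = sr.simulate_acquisition(phantom, protocol, seed=0)
    caipi = sr.make_caipi_schedule(protocol, kspace.pattern_ref)
    return protocol, phantom, kspace, calib, kspace.pattern_ref, caipi
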