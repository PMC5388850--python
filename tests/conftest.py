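import numpy as np
import pytest

from quspred.containers import RFFrame, ROIMask
from quspred.simulate import PulseModel, make_scatterer_phantom, simulate_rf_frame


@pytest.fixture(scope="session")
def pulse():
    return PulseModel()


@pytest.fixture(scope="session")
def frame_pair(pulse):
    """A homogeneous sample frame (alpha=1.0, a_eff=25 um) and the matched
    reference-phantom frame (alpha=0.5, near-Rayleigh), shared across tests."""
    n_lines, pitch, depth = 64, 0.3, 32.0
    n_samples = int(np.ceil(2 * depth * 1e-3 / 1540 * 40e6)) + 96
    ref = simulate_rf_frame(
        make_scatterer_phantom(depth, n_lines * pitch, 60, 5.0, 0.0, 0.5, seed=999),
        pulse,
        n_lines,
        pitch,
        n_samples=n_samples,
    )
    sam = simulate_rf_frame(
        make_scatterer_phantom(depth, n_lines * pitch, 60, 25.0, 0.0, 1.0, seed=1),
        pulse,
        n_lines,
        pitch,
        n_samples=n_samples,
    )
    return sam, ref


@pytest.fixture(scope="session")
def core_mask(frame_pair):
    """Elliptical tumour-core mask centred in the sample frame."""
    sam, _ = frame_pair
    ax, lat = sam.pixel_dims_mm
    rows = np.arange(sam.n_samples)[:, None] * ax
    cols = np.arange(sam.n_lines)[None, :] * lat
    cz, cx = 16.0, sam.n_lines * lat / 2.0
    return ROIMask(((rows - cz) / 7.0) ** 2 + ((cols - cx) / 4.5) ** 2 <= 1.0, "core")


@pytest.fixture
def flat_geometry_frame():
    """Zero-signal frame with 0.1 mm square pixels, for geometry tests."""
    fs = 1540.0 / (2 * 0.1e-3)  # axial step exactly 0.1 mm
    return RFFrame(np.zeros((350, 350)), sampling_rate_hz=fs, line_pitch_mm=0.1)
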