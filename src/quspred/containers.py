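"""Core in-memory containers for RF echo data, B-mode images and ROI masks.

The acquisition geometry follows a linear-array probe: the RF frame is a
rectilinear grid of axial samples (rows) by scan lines (columns), so the
B-mode grid coincides with the RF grid and masks are defined directly on it
(no scan conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert


class FormatError(ValueError):
    """A container or file does not satisfy the documented layout."""


@dataclass
class RFFrame:
    """Raw pulse-echo radiofrequency data with its acquisition geometry.

    Parameters
    ----------
    samples
        2-D array, shape ``(n_axial_samples, n_lines)``, linear amplitude.
    sampling_rate_hz
        Axial sampling rate of the digitizer (e.g. 40 MHz).
    line_pitch_mm
        Lateral spacing between adjacent scan lines (element pitch).
    speed_of_sound_m_s
        Assumed propagation speed used to map samples to depth.
    axial_origin_mm
        Depth of the first sample row.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    line_pitch_mm: float
    speed_of_sound_m_s: float = 1540.0
    axial_origin_mm: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] < 1 or self.samples.shape[0] < 1:
            raise FormatError(
                f"RF samples must be a non-empty 2-D array, got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("RF samples contain non-finite values")
        if self.sampling_rate_hz <= 0:
            raise FormatError("sampling_rate_hz must be positive")
        if self.line_pitch_mm <= 0:
            raise FormatError("line_pitch_mm must be positive")
        if self.speed_of_sound_m_s <= 0:
            raise FormatError("speed_of_sound_m_s must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_step_mm(self) -> float:
        """Depth increment per axial sample: c / (2 fs), in mm."""
        return self.speed_of_sound_m_s / (2.0 * self.sampling_rate_hz) * 1000.0

    @property
    def pixel_dims_mm(self) -> tuple[float, float]:
        """(axial, lateral) pixel size in mm of the RF/B-mode grid."""
        return (self.axial_step_mm, self.line_pitch_mm)

    def depth_mm(self, sample_index: np.ndarray | int) -> np.ndarray | float:
        """Depth of an axial sample index (mm)."""
        return self.axial_origin_mm + np.asarray(sample_index) * self.axial_step_mm

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(axial, lateral) physical extent of the frame in mm."""
        return (self.n_samples * self.axial_step_mm, self.n_lines * self.line_pitch_mm)


@dataclass
class BModeImage:
    """Log-compressed envelope image, normalized so the peak pixel is 0 dB."""

    pixels: np.ndarray
    axial_pixel_mm: float
    lateral_pixel_mm: float

    def __post_init__(self) -> None:
        if self.axial_pixel_mm <= 0 or self.lateral_pixel_mm <= 0:
            raise FormatError("pixel sizes must be positive")


@dataclass
class ROIMask:
    """Binary region mask on the B-mode grid (row = axial, col = lateral)."""

    mask: np.ndarray
    region: str = "core"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("mask must be 2-D")
        if self.region == "core" and not self.mask.any():
            raise FormatError("core mask must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def compute_bmode(frame: RFFrame) -> BModeImage:
    """Log-compress the analytic envelope of an RF frame.

    Pixels are ``20 log10(envelope / max envelope)`` so the brightest pixel
    is exactly 0 dB; an all-zero frame has no envelope and is rejected.
    """
    env = np.abs(hilbert(frame.samples, axis=0))
    peak = env.max()
    if peak <= 0:
        raise ValueError("cannot form a B-mode image from an all-zero frame")
    with np.errstate(divide="ignore"):
        pixels = 20.0 * np.log10(env / peak)
    ax, lat = frame.pixel_dims_mm
    return BModeImage(pixels=pixels, axial_pixel_mm=ax, lateral_pixel_mm=lat)
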