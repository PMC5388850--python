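"""Power-spectrum estimation, reference-phantom normalization, attenuation.

The estimation chain per analysis block is: average windowed periodograms
over the block's scan-line segments; divide by the reference-phantom
spectrum at the same depth (in dB: subtract) to cancel the system transfer
function; estimate the attenuation slope of the whole core ROI by the
spectral difference method; point-compensate each block's normalized
spectrum for the attenuation accumulated over the overlying tissue path;
finally fit a least-squares line over the usable band to obtain the
midband fit (MBF), spectral slope (SS) and 0-MHz intercept (SI).

Attenuation bookkeeping: an attenuation coefficient ``alpha`` in
dB/cm/MHz is one-way, so a round trip to depth ``z`` cm attenuates the
echo power spectrum by ``2 * alpha * f * z`` dB at frequency ``f`` MHz.
This convention is used consistently by the simulator, the spectral
difference estimator and the point compensation below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .containers import RFFrame
from .roi import AnalysisBlock, ROIMask, tile_blocks

#: Fallback usable band when no pulse model is declared (6 MHz probe).
DEFAULT_BAND_MHZ = (3.0, 8.0)

#: Round-trip power attenuation in dB per (dB/cm/MHz x MHz x cm).
TWO_WAY_DB = 2.0


@dataclass
class NormalizedSpectrum:
    """A per-block power spectrum in dB on a frequency grid.

    ``freq_mhz`` spans the full grid; ``band_mhz`` marks the usable
    sub-band on which fits are performed.  ``depth_mm`` is the block-centre
    depth, and ``path_mm`` the overlying tissue path used for attenuation
    compensation (measured from the shallowest row of the parent ROI).
    """

    freq_mhz: np.ndarray
    power_db: np.ndarray
    band_mhz: tuple[float, float] = DEFAULT_BAND_MHZ
    depth_mm: float = 0.0
    path_mm: float = 0.0

    def __post_init__(self) -> None:
        self.freq_mhz = np.asarray(self.freq_mhz, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.freq_mhz.shape != self.power_db.shape:
            raise ValueError("frequency grid and power must have equal shapes")
        lo, hi = self.band_mhz
        if not (lo < hi):
            raise ValueError("band must satisfy f_lo < f_hi")
        if lo < self.freq_mhz.min() - 1e-9 or hi > self.freq_mhz.max() + 1e-9:
            raise ValueError("usable band must lie within the frequency grid")

    @property
    def band_mask(self) -> np.ndarray:
        lo, hi = self.band_mhz
        return (self.freq_mhz >= lo - 1e-12) & (self.freq_mhz <= hi + 1e-12)

    def in_band(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.band_mask
        return self.freq_mhz[m], self.power_db[m]


@dataclass
class SpectralFit:
    """Linear-fit parameters of a normalized spectrum over the usable band."""

    mbf_db: float
    ss_db_mhz: float
    si_db: float
    band_mhz: tuple[float, float]


@dataclass
class ACEEstimate:
    """Attenuation coefficient estimate for one core ROI (dB/cm/MHz)."""

    ace_db_cm_mhz: float
    depth_span_cm: float
    n_depths: int
    residual_db: float


def block_power_spectrum(
    frame: RFFrame,
    block: AnalysisBlock,
    window: str = "hann",
    n_fft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean windowed periodogram over a block's scan-line segments.

    Returns ``(freq_mhz, power)`` with *linear* power units; callers convert
    to dB after any averaging across blocks.
    """
    r0, c0 = block.sample_start, block.line_start
    r1, c1 = r0 + block.n_samples_axial, c0 + block.n_lines
    if r0 < 0 or c0 < 0 or r1 > frame.n_samples or c1 > frame.n_lines:
        raise ValueError("analysis block extends outside the RF frame")
    segment = frame.samples[r0:r1, c0:c1]
    n = segment.shape[0]
    if n < 4:
        raise ValueError("analysis block shorter than the minimum window length")
    if window == "hann":
        w = hann(n, sym=False)
    elif window in ("boxcar", "rect", "none"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    if n_fft is None:
        n_fft = n
    spec = np.fft.rfft(segment * w[:, None], n=n_fft, axis=0)
    power = np.mean(np.abs(spec) ** 2, axis=1) / np.sum(w**2)
    freq_mhz = np.fft.rfftfreq(n_fft, d=1.0 / frame.sampling_rate_hz) / 1e6
    return freq_mhz, power


def normalize_spectrum(
    sample_power: np.ndarray,
    reference_power: np.ndarray,
    freq_mhz: np.ndarray,
    band_mhz: tuple[float, float] = DEFAULT_BAND_MHZ,
    depth_mm: float = 0.0,
    path_mm: float = 0.0,
) -> NormalizedSpectrum:
    """Reference-phantom normalization: ``10 log10(S_sample / S_reference)``.

    Dividing by a phantom spectrum acquired with the same system at the same
    depth cancels the transfer function and diffraction terms, leaving the
    tissue-to-phantom backscatter ratio (times residual attenuation).
    """
    sample_power = np.asarray(sample_power, dtype=float)
    reference_power = np.asarray(reference_power, dtype=float)
    freq_mhz = np.asarray(freq_mhz, dtype=float)
    band = (freq_mhz >= band_mhz[0]) & (freq_mhz <= band_mhz[1])
    if not band.any():
        raise ValueError("usable band contains no frequency samples")
    if np.any(reference_power[band] <= 0):
        raise ZeroDivisionError("reference spectrum non-positive inside the usable band")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_db = 10.0 * np.log10(
            np.where(reference_power > 0, sample_power / np.maximum(reference_power, 1e-300), np.nan)
        )
    return NormalizedSpectrum(
        freq_mhz=freq_mhz,
        power_db=ratio_db,
        band_mhz=band_mhz,
        depth_mm=depth_mm,
        path_mm=path_mm,
    )


def fit_linear_spectrum(spec: NormalizedSpectrum) -> SpectralFit:
    """Least-squares line over the usable band.

    SS is the slope in dB/MHz, SI the intercept at 0 MHz, and MBF the value
    of the fitted line at the band centre, so MBF = SS * f_c + SI exactly.
    """
    f, s = spec.in_band()
    ok = np.isfinite(s)
    f, s = f[ok], s[ok]
    if f.size < 2 or np.ptp(f) == 0:
        raise ValueError("need at least two distinct in-band frequencies to fit a line")
    slope, intercept = np.polyfit(f, s, 1)
    f_c = 0.5 * (spec.band_mhz[0] + spec.band_mhz[1])
    return SpectralFit(
        mbf_db=float(slope * f_c + intercept),
        ss_db_mhz=float(slope),
        si_db=float(intercept),
        band_mhz=spec.band_mhz,
    )


def attenuation_db(alpha_db_cm_mhz: float, freq_mhz: np.ndarray, path_cm: float) -> np.ndarray:
    """Round-trip power-spectrum attenuation in dB at depth ``path_cm``."""
    return TWO_WAY_DB * alpha_db_cm_mhz * np.asarray(freq_mhz) * path_cm


def correct_attenuation(
    spec: NormalizedSpectrum,
    ace_db_cm_mhz: float,
    alpha_reference_db_cm_mhz: float,
    path_cm: float | None = None,
) -> NormalizedSpectrum:
    """Point-compensate a normalized spectrum for residual attenuation.

    The reference division removes the phantom's attenuation, leaving the
    excess ``ace - alpha_reference`` accumulated over the overlying tissue
    path; the compensation adds it back so the backscatter fit sees an
    attenuation-free spectrum.
    """
    if path_cm is None:
        path_cm = spec.path_mm / 10.0
    if path_cm < 0:
        raise ValueError("tissue path must be non-negative")
    delta = ace_db_cm_mhz - alpha_reference_db_cm_mhz
    corrected = spec.power_db + attenuation_db(delta, spec.freq_mhz, path_cm)
    return NormalizedSpectrum(
        freq_mhz=spec.freq_mhz,
        power_db=corrected,
        band_mhz=spec.band_mhz,
        depth_mm=spec.depth_mm,
        path_mm=spec.path_mm,
    )


def _mean_reference_spectrum(
    reference: RFFrame, sample_rows: tuple[int, int], n_axial: int, window: str
) -> tuple[np.ndarray, np.ndarray]:
    """Average the reference phantom's periodograms at a given depth over
    every lateral position, shrinking spectral variance of the divisor."""
    r0 = sample_rows[0]
    block = AnalysisBlock(
        sample_start=r0,
        line_start=0,
        n_samples_axial=n_axial,
        n_lines=reference.n_lines,
        depth_mm=float(reference.depth_mm(r0 + n_axial // 2)),
        region="reference",
    )
    return block_power_spectrum(reference, block, window=window)


def estimate_ace(
    frame: RFFrame,
    core: ROIMask,
    reference: RFFrame,
    alpha_reference_db_cm_mhz: float,
    band_mhz: tuple[float, float] = DEFAULT_BAND_MHZ,
    block_mm: float = 2.0,
    overlap: float = 0.8,
    window: str = "hann",
    min_depth_span_mm: float = 10.0,
) -> ACEEstimate:
    """Spectral difference method: one attenuation estimate per core ROI.

    For each block-depth within the core, the mean sample spectrum is
    divided by the reference spectrum at the same depth.  The dB ratio
    decays linearly with depth at a rate ``-2 (alpha - alpha_ref) f`` per
    cm; regressing that decay rate against frequency yields the excess
    attenuation slope, and adding the known phantom slope gives the ACE.
    """
    blocks = tile_blocks(core, frame, block_mm=block_mm, overlap=overlap)
    if not blocks:
        raise ValueError("core ROI too small to tile any analysis block")
    depths = sorted({b.sample_start for b in blocks})
    span_mm = (depths[-1] - depths[0]) * frame.axial_step_mm
    if span_mm < min_depth_span_mm:
        raise ValueError(
            f"core depth span {span_mm:.1f} mm below the minimum "
            f"{min_depth_span_mm:.1f} mm required for attenuation estimation"
        )
    by_row: dict[int, list[AnalysisBlock]] = {}
    for b in blocks:
        by_row.setdefault(b.sample_start, []).append(b)

    n_axial = blocks[0].n_samples_axial
    freq = None
    depth_cm, ratios = [], []
    for row in depths:
        row_blocks = by_row[row]
        powers = []
        for b in row_blocks:
            f, p = block_power_spectrum(frame, b, window=window)
            powers.append(p)
            freq = f
        mean_power = np.mean(powers, axis=0)
        _, ref_power = _mean_reference_spectrum(reference, (row, row + n_axial), n_axial, window)
        band = (freq >= band_mhz[0]) & (freq <= band_mhz[1])
        if np.any(ref_power[band] <= 0) or np.any(mean_power[band] <= 0):
            continue
        ratios.append(10.0 * np.log10(mean_power[band] / ref_power[band]))
        depth_cm.append(float(frame.depth_mm(row + n_axial / 2)) / 10.0)
    if len(depth_cm) < 3:
        raise ValueError("insufficient usable depths for the spectral difference fit")

    freq_band = freq[(freq >= band_mhz[0]) & (freq <= band_mhz[1])]
    depth_cm = np.asarray(depth_cm)
    ratios = np.vstack(ratios)  # depths x frequencies
    # Per-frequency slope of the dB ratio versus depth (dB/cm).
    slopes = np.polyfit(depth_cm, ratios, 1)[0]
    # slope(f) = -TWO_WAY_DB * delta_alpha * f  -> regress through the origin.
    delta_alpha = -float(freq_band @ slopes) / (TWO_WAY_DB * float(freq_band @ freq_band))
    fitted = -TWO_WAY_DB * delta_alpha * freq_band
    residual = float(np.sqrt(np.mean((slopes - fitted) ** 2)))
    return ACEEstimate(
        ace_db_cm_mhz=alpha_reference_db_cm_mhz + delta_alpha,
        depth_span_cm=float(depth_cm.max() - depth_cm.min()),
        n_depths=len(depth_cm),
        residual_db=residual,
    )
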