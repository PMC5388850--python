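"""Synthetic inputs: scatterer phantoms, pulse-echo RF frames, spectrum-level
oracles, two-class feature cohorts and censored survival cohorts.

The RF simulator is deliberately simple — a linear-array geometry where each
scan line accepts the scatterers within half a pitch laterally (Gaussian
lateral weighting), each scatterer echoing at its round-trip delay 2z/c.
Echo spectra are shaped by the pulse, by the square root of the Gaussian
form-factor backscatter model (so the *power* spectrum follows the model
used for fitting), and by frequency-linear attenuation applied per depth
segment in the frequency domain.  It produces fully developed speckle at
sufficient scatterer density without attempting diffraction accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len

from .backscatter import backscatter_model_db, gaussian_form_factor
from .containers import RFFrame
from .spectral import TWO_WAY_DB, NormalizedSpectrum


@dataclass
class PulseModel:
    """Gaussian-modulated sinusoid pulse, parameterized by its -6 dB
    fractional bandwidth (amplitude spectrum)."""

    center_frequency_hz: float = 6e6
    fractional_bandwidth: float = 0.6
    sampling_rate_hz: float = 40e6
    speed_of_sound_m_s: float = 1540.0

    def __post_init__(self) -> None:
        if not (0 < self.fractional_bandwidth < 2):
            raise ValueError("fractional bandwidth must lie in (0, 2)")
        if self.sampling_rate_hz <= 4 * self.center_frequency_hz:
            raise ValueError("sampling rate must exceed 4x the centre frequency")

    @property
    def bandwidth_hz(self) -> float:
        return self.fractional_bandwidth * self.center_frequency_hz

    @property
    def sigma_f_hz(self) -> float:
        # exp(-(B/2)^2 / (2 sigma^2)) = 10^(-6/20)  at the -6 dB edges
        return self.bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(10 ** 0.3)))

    @property
    def band_mhz(self) -> tuple[float, float]:
        """-6 dB band of the pulse amplitude spectrum, in MHz."""
        half = self.bandwidth_hz / 2.0
        return (
            (self.center_frequency_hz - half) / 1e6,
            (self.center_frequency_hz + half) / 1e6,
        )

    def amplitude_spectrum(self, freq_hz: np.ndarray) -> np.ndarray:
        f = np.asarray(freq_hz, dtype=float)
        return np.exp(-((f - self.center_frequency_hz) ** 2) / (2.0 * self.sigma_f_hz**2))


@dataclass
class ScattererPhantom:
    """A 2-D random field of identical scatterers with known ground truth.

    ``effective_radius_um`` is the ground truth for ASD/2,
    ``acoustic_concentration_db`` for AAC (dB, reference-relative), and
    ``attenuation_slope_db_cm_mhz`` for the ACE.
    """

    extent_axial_mm: float
    extent_lateral_mm: float
    positions_mm: np.ndarray  # (n, 2): axial z, lateral x
    effective_radius_um: float
    acoustic_concentration_db: float
    number_density_per_mm2: float
    attenuation_slope_db_cm_mhz: float
    seed: int

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float).reshape(-1, 2)
        if self.positions_mm.size:
            z, x = self.positions_mm[:, 0], self.positions_mm[:, 1]
            if z.min() < 0 or z.max() > self.extent_axial_mm or x.min() < 0 or x.max() > self.extent_lateral_mm:
                raise ValueError("scatterer positions outside the phantom extent")
        if self.attenuation_slope_db_cm_mhz < 0:
            raise ValueError("attenuation slope must be non-negative")

    @property
    def n_scatterers(self) -> int:
        return self.positions_mm.shape[0]


def make_scatterer_phantom(
    extent_axial_mm: float,
    extent_lateral_mm: float,
    number_density_per_mm2: float,
    effective_radius_um: float = 25.0,
    acoustic_concentration_db: float = 0.0,
    attenuation_slope_db_cm_mhz: float = 0.5,
    seed: int = 0,
) -> ScattererPhantom:
    """Uniformly random scatterer field; count = round(density x area)."""
    if extent_axial_mm <= 0 or extent_lateral_mm <= 0:
        raise ValueError("phantom extents must be positive")
    if number_density_per_mm2 < 0:
        raise ValueError("scatterer density must be non-negative")
    area = extent_axial_mm * extent_lateral_mm
    n = int(round(number_density_per_mm2 * area))
    rng = np.random.default_rng(seed)
    positions = rng.uniform([0.0, 0.0], [extent_axial_mm, extent_lateral_mm], size=(n, 2))
    return ScattererPhantom(
        extent_axial_mm=extent_axial_mm,
        extent_lateral_mm=extent_lateral_mm,
        positions_mm=positions,
        effective_radius_um=effective_radius_um,
        acoustic_concentration_db=acoustic_concentration_db,
        number_density_per_mm2=number_density_per_mm2,
        attenuation_slope_db_cm_mhz=attenuation_slope_db_cm_mhz,
        seed=seed,
    )


def simulate_rf_frame(
    phantom: ScattererPhantom,
    pulse: PulseModel,
    n_lines: int,
    line_pitch_mm: float,
    n_samples: int | None = None,
    noise_rms: float = 0.0,
    seed: int | None = None,
    segment_mm: float = 1.0,
) -> RFFrame:
    """Simulate one pulse-echo RF frame of a scatterer phantom.

    Each scan line j (centred at (j + 1/2) * pitch) accepts the scatterers
    within +-pitch/2 laterally, weighted by a Gaussian beam profile.  A
    scatterer at depth z places a weighted impulse at the round-trip delay
    sample round(2 z / c * fs); impulses are then filtered in the frequency
    domain per ``segment_mm`` depth segment with the zero-phase transfer

        H_z(f) = P(f) * f_MHz^2 * sqrt(FF(f)) * 10^(-2 alpha f_MHz z_cm / 20),

    i.e. pulse spectrum, amplitude-domain backscatter model, and two-way
    attenuation accumulated to the segment depth.  Optional additive white
    Gaussian noise models the electronics.
    """
    if n_lines < 1:
        raise ValueError("need at least one scan line")
    if line_pitch_mm <= 0:
        raise ValueError("line pitch must be positive")
    fs = pulse.sampling_rate_hz
    c = pulse.speed_of_sound_m_s

    z = phantom.positions_mm[:, 0]
    x = phantom.positions_mm[:, 1]
    delay_idx = np.round(2.0 * z * 1e-3 / c * fs).astype(int) if z.size else np.empty(0, dtype=int)
    # Pulse kernel support: keep ~6 temporal sigmas on either side.
    sigma_t_samples = fs / (2.0 * np.pi * pulse.sigma_f_hz)
    pad = int(np.ceil(8 * sigma_t_samples)) + 8
    if n_samples is None:
        deepest = int(delay_idx.max()) if delay_idx.size else int(
            np.ceil(2.0 * phantom.extent_axial_mm * 1e-3 / c * fs)
        )
        n_samples = deepest + pad
    elif delay_idx.size and delay_idx.max() >= n_samples:
        raise ValueError(
            f"frame of {n_samples} samples too short for the deepest scatterer "
            f"(delay sample {int(delay_idx.max())})"
        )

    impulses = np.zeros((n_samples, n_lines))
    if delay_idx.size:
        line = np.floor(x / line_pitch_mm).astype(int)
        keep = (line >= 0) & (line < n_lines) & (delay_idx < n_samples)
        line = line[keep]
        idx = delay_idx[keep]
        offset = x[keep] - (line + 0.5) * line_pitch_mm
        sigma_l = line_pitch_mm / 2.0
        weight = np.exp(-(offset**2) / (2.0 * sigma_l**2))
        # Density-normalized amplitude keeps the mean power spectrum (and
        # hence the fitted AAC) independent of the scatterer count.
        amp = 10.0 ** (phantom.acoustic_concentration_db / 20.0)
        if phantom.number_density_per_mm2 > 0:
            amp /= np.sqrt(phantom.number_density_per_mm2)
        np.add.at(impulses, (idx, line), amp * weight)

    n_fft = next_fast_len(n_samples + 2 * pad)
    freq_hz = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    freq_mhz = freq_hz / 1e6
    base = (
        pulse.amplitude_spectrum(freq_hz)
        * freq_mhz**2
        * np.sqrt(gaussian_form_factor(freq_mhz, phantom.effective_radius_um, c))
    )

    rf = np.zeros((n_samples, n_lines))
    if delay_idx.size and idx.size:
        depth_mm_axis = np.arange(n_samples) * c / (2.0 * fs) * 1e3
        seg_of_row = np.floor(depth_mm_axis / segment_mm).astype(int)
        for seg in np.unique(seg_of_row[idx]):
            rows = seg_of_row == seg
            seg_imp = np.where(rows[:, None], impulses, 0.0)
            if not np.any(seg_imp):
                continue
            z_cm = (seg + 0.5) * segment_mm / 10.0
            atten = 10.0 ** (
                -TWO_WAY_DB * phantom.attenuation_slope_db_cm_mhz * freq_mhz * z_cm / 20.0
            )
            spec = np.fft.rfft(seg_imp, n=n_fft, axis=0) * (base * atten)[:, None]
            rf += np.fft.irfft(spec, n=n_fft, axis=0)[:n_samples]

    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        rf = rf + rng.normal(0.0, noise_rms, size=rf.shape)
    return RFFrame(
        samples=rf,
        sampling_rate_hz=fs,
        line_pitch_mm=line_pitch_mm,
        speed_of_sound_m_s=c,
    )


def synthesize_block_spectrum(
    a_eff_um: float,
    aac_db: float,
    band_mhz: tuple[float, float] = (3.0, 8.0),
    noise_db: float = 0.0,
    seed: int | None = None,
    n_points: int = 64,
    c_m_s: float = 1540.0,
) -> NormalizedSpectrum:
    """Spectrum-level oracle: the Gaussian form-factor backscatter model
    evaluated on a frequency grid (dB) plus optional zero-mean dB noise.

    This bypasses RF simulation entirely, providing an exact inverse-test
    substrate for the model fit.
    """
    lo, hi = band_mhz
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < f_lo < f_hi")
    if n_points < 3:
        raise ValueError("need at least three frequency points")
    freq = np.linspace(lo, hi, n_points)
    power = backscatter_model_db(freq, a_eff_um, aac_db, c_m_s)
    if noise_db > 0:
        rng = np.random.default_rng(seed)
        power = power + rng.normal(0.0, noise_db, size=power.shape)
    return NormalizedSpectrum(freq_mhz=freq, power_db=power, band_mhz=band_mhz)


# ---------------------------------------------------------------------------
# Patient-level cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Two-class multivariate-normal feature cohort specification.

    Class sizes default to the 42 good / 14 poor imbalance of the study
    population this package emulates.
    """

    feature_names: tuple[str, ...]
    mean_good: np.ndarray
    mean_poor: np.ndarray
    covariance: np.ndarray | None = None
    n_good: int = 42
    n_poor: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_good = np.asarray(self.mean_good, dtype=float)
        self.mean_poor = np.asarray(self.mean_poor, dtype=float)
        d = len(self.feature_names)
        if self.mean_good.shape != (d,) or self.mean_poor.shape != (d,):
            raise ValueError("class means must have one entry per feature")
        if self.covariance is None:
            self.covariance = np.eye(d)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (d, d) or not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be a symmetric d x d matrix")
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        if self.n_good < 1 or self.n_poor < 1:
            raise ValueError("both classes need at least one patient")


def generate_feature_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a labelled two-class cohort from class-conditional Gaussians."""
    rng = np.random.default_rng(spec.seed)
    X_good = rng.multivariate_normal(spec.mean_good, spec.covariance, size=spec.n_good)
    X_poor = rng.multivariate_normal(spec.mean_poor, spec.covariance, size=spec.n_poor)
    n = spec.n_good + spec.n_poor
    ids = [f"P{i+1:03d}" for i in range(n)]
    table = pd.DataFrame(np.vstack([X_good, X_poor]), index=ids, columns=list(spec.feature_names))
    table.index.name = "patient_id"
    labels = pd.Series(["good"] * spec.n_good + ["poor"] * spec.n_poor, index=ids, name="response_gp")
    return table, labels


def generate_survival_cohort(
    n_per_group: int | dict[str, int],
    hazards: dict[str, float],
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with independent exponential censoring.

    ``censor_rate`` is the expected fraction of censored records per group;
    the censoring hazard is ``lambda * rate / (1 - rate)`` so that
    P(censor before event) equals the requested rate.
    """
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    for g, lam in hazards.items():
        if lam <= 0:
            raise ValueError(f"hazard for group {g!r} must be positive")
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in hazards}
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group in sorted(hazards):
        lam = hazards[group]
        n = n_per_group[group]
        event_t = rng.exponential(1.0 / lam, size=n)
        if censor_rate > 0:
            mu = lam * censor_rate / (1.0 - censor_rate)
            censor_t = rng.exponential(1.0 / mu, size=n)
        else:
            censor_t = np.full(n, np.inf)
        months = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        for t, e in zip(months, event):
            i += 1
            rows.append({"patient_id": f"S{i:03d}", "months": float(t), "event": int(e), "group": group})
    return pd.DataFrame(rows)
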