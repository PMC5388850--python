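"""Gaussian-form-factor backscatter model fitting (ASD and AAC estimation).

The effective scatterer is modelled by the Gaussian form factor in the
Insana-Hall convention,

    FF(f) = exp(-0.827 k^2 a_eff^2),   k = 2 pi f / c,

so the backscatter power model in dB is

    M(f) = AAC + 10 log10(f_MHz^4) + 10 log10 FF(f).

AAC is reported in dB relative to the reference phantom's concentration
(no absolute calibration); ASD = 2 a_eff in micrometres.  Fitting is a
deterministic coarse grid over a_eff with the dB offset (AAC) closed-form
per candidate, followed by bounded scalar refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .roi import AnalysisBlock, ParametricImage, assemble_parametric_image
from .spectral import NormalizedSpectrum

GAUSSIAN_FF_CONSTANT = 0.827

#: Default coarse-grid bounds and step for a_eff, in micrometres.
DEFAULT_A_GRID = (1.0, 150.0, 1.0)


@dataclass
class BackscatterEstimate:
    """Per-block effective scatterer diameter and acoustic concentration."""

    asd_um: float
    aac_db: float
    residual_db: float
    at_bound: bool = False


def gaussian_form_factor(freq_mhz: np.ndarray, a_eff_um: float, c_m_s: float = 1540.0) -> np.ndarray:
    """Gaussian form factor at the given frequencies (linear scale)."""
    k = 2.0 * np.pi * np.asarray(freq_mhz) * 1e6 / c_m_s  # rad/m
    a = a_eff_um * 1e-6
    return np.exp(-GAUSSIAN_FF_CONSTANT * (k * a) ** 2)


def backscatter_model_db(
    freq_mhz: np.ndarray, a_eff_um: float, aac_db: float, c_m_s: float = 1540.0
) -> np.ndarray:
    """Backscatter power model in dB: Rayleigh f^4 times the Gaussian form factor."""
    freq_mhz = np.asarray(freq_mhz, dtype=float)
    with np.errstate(divide="ignore"):
        f4 = 40.0 * np.log10(freq_mhz)
    ff_db = 10.0 * np.log10(gaussian_form_factor(freq_mhz, a_eff_um, c_m_s))
    return aac_db + f4 + ff_db


def apparent_backscatter(
    spec: NormalizedSpectrum,
    ref_a_eff_um: float,
    ref_aac_db: float = 0.0,
    c_m_s: float = 1540.0,
) -> NormalizedSpectrum:
    """Convert a normalized (tissue/phantom ratio) spectrum to an apparent
    backscatter spectrum by adding back the reference phantom's known model."""
    ref_db = backscatter_model_db(spec.freq_mhz, ref_a_eff_um, ref_aac_db, c_m_s)
    return NormalizedSpectrum(
        freq_mhz=spec.freq_mhz,
        power_db=spec.power_db + ref_db,
        band_mhz=spec.band_mhz,
        depth_mm=spec.depth_mm,
        path_mm=spec.path_mm,
    )


def _shape_db(freq_mhz: np.ndarray, a_eff_um: np.ndarray, c_m_s: float) -> np.ndarray:
    """Model shape (without the AAC offset) for a grid of candidate radii.

    Returns shape ``(n_candidates, n_freq)``.
    """
    k = 2.0 * np.pi * freq_mhz * 1e6 / c_m_s
    a = np.atleast_1d(a_eff_um)[:, None] * 1e-6
    ff_db = -GAUSSIAN_FF_CONSTANT * (k[None, :] * a) ** 2 * (10.0 / np.log(10.0))
    return 40.0 * np.log10(freq_mhz)[None, :] + ff_db


def fit_gaussian_form_factor(
    spec: NormalizedSpectrum,
    c_m_s: float = 1540.0,
    a_grid: tuple[float, float, float] = DEFAULT_A_GRID,
) -> BackscatterEstimate:
    """Fit (a_eff, AAC) to an attenuation-corrected apparent backscatter
    spectrum by least squares over the usable band.

    The AAC is the mean dB offset between spectrum and shape for each
    candidate a_eff (closed form), so only a_eff is searched: coarse grid,
    then Brent refinement bracketed by the best candidate's neighbours.
    An a_eff at the grid edge is flagged (``at_bound``) but still returned.
    """
    f, s = spec.in_band()
    ok = np.isfinite(s)
    f, s = f[ok], s[ok]
    if f.size < 3:
        raise ValueError("need at least three in-band frequencies to fit the model")
    lo, hi, step = a_grid
    grid = np.arange(lo, hi + 0.5 * step, step)

    def rms(a: float) -> float:
        shape = _shape_db(f, np.array([a]), c_m_s)[0]
        offset = float(np.mean(s - shape))
        return float(np.sqrt(np.mean((s - shape - offset) ** 2)))

    shapes = _shape_db(f, grid, c_m_s)
    offsets = np.mean(s[None, :] - shapes, axis=1)
    resid = np.sqrt(np.mean((s[None, :] - shapes - offsets[:, None]) ** 2, axis=1))
    i = int(np.argmin(resid))
    a_lo = grid[max(i - 1, 0)]
    a_hi = grid[min(i + 1, grid.size - 1)]
    if a_hi > a_lo:
        res = minimize_scalar(rms, bounds=(a_lo, a_hi), method="bounded", options={"xatol": 1e-4})
        a_best = float(res.x)
        r_best = float(res.fun)
        if r_best > resid[i]:  # keep the grid point if refinement did not help
            a_best, r_best = float(grid[i]), float(resid[i])
    else:
        a_best, r_best = float(grid[i]), float(resid[i])
    shape = _shape_db(f, np.array([a_best]), c_m_s)[0]
    aac = float(np.mean(s - shape))
    at_bound = a_best <= lo + 1e-6 or a_best >= hi - 1e-6
    return BackscatterEstimate(asd_um=2.0 * a_best, aac_db=aac, residual_db=r_best, at_bound=at_bound)


def fit_gaussian_form_factor_batch(
    freq_mhz: np.ndarray,
    spectra_db: np.ndarray,
    c_m_s: float = 1540.0,
    a_grid: tuple[float, float, float] = DEFAULT_A_GRID,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized grid fit for many spectra at once (parametric imaging).

    Grid search plus parabolic interpolation of the squared residual around
    the best candidate; accuracy is limited by the grid step, which is
    ample for block-level maps.  Returns ``(asd_um, aac_db, residual_db,
    at_bound)`` arrays, one entry per row of ``spectra_db``.
    """
    spectra_db = np.atleast_2d(np.asarray(spectra_db, dtype=float))
    lo, hi, step = a_grid
    grid = np.arange(lo, hi + 0.5 * step, step)
    shapes = _shape_db(freq_mhz, grid, c_m_s)  # (n_grid, n_freq)
    diff = spectra_db[:, None, :] - shapes[None, :, :]
    offsets = diff.mean(axis=2)
    sq = ((diff - offsets[..., None]) ** 2).mean(axis=2)  # (n_spec, n_grid)
    best = np.argmin(sq, axis=1)

    # Parabolic refinement where the minimum is interior.
    a_best = grid[best].astype(float)
    interior = (best > 0) & (best < grid.size - 1)
    if interior.any():
        idx = np.flatnonzero(interior)
        y0 = sq[idx, best[idx] - 1]
        y1 = sq[idx, best[idx]]
        y2 = sq[idx, best[idx] + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(denom > 0, 0.5 * (y0 - y2) / np.maximum(denom, 1e-30), 0.0)
        a_best[idx] = grid[best[idx]] + np.clip(shift, -1.0, 1.0) * step

    shapes_best = _shape_db(freq_mhz, a_best, c_m_s)
    aac = (spectra_db - shapes_best).mean(axis=1)
    residual = np.sqrt(((spectra_db - shapes_best - aac[:, None]) ** 2).mean(axis=1))
    at_bound = (best == 0) | (best == grid.size - 1)
    return 2.0 * a_best, aac, residual, at_bound


def map_backscatter(
    blocks: list[AnalysisBlock],
    corrected_spectra: list[NormalizedSpectrum],
    c_m_s: float = 1540.0,
    ref_a_eff_um: float = 5.0,
    ref_aac_db: float = 0.0,
    a_grid: tuple[float, float, float] = DEFAULT_A_GRID,
    step_mm: float = 0.4,
) -> tuple[ParametricImage, ParametricImage]:
    """Per-block ASD/AAC estimates assembled into two parametric images."""
    if len(blocks) != len(corrected_spectra):
        raise ValueError("one spectrum required per analysis block")
    if not blocks:
        empty = np.empty((0, 0))
        return (
            ParametricImage(empty, empty.astype(bool), "ASD", step_mm),
            ParametricImage(empty.copy(), empty.astype(bool), "AAC", step_mm),
        )
    band = corrected_spectra[0].band_mask
    freq = corrected_spectra[0].freq_mhz[band]
    ref_db = backscatter_model_db(freq, ref_a_eff_um, ref_aac_db, c_m_s)
    rows = np.vstack([sp.power_db[band] + ref_db for sp in corrected_spectra])
    finite = np.all(np.isfinite(rows), axis=1)
    asd = np.full(len(blocks), np.nan)
    aac = np.full(len(blocks), np.nan)
    if finite.any():
        a, c_db, _, _ = fit_gaussian_form_factor_batch(freq, rows[finite], c_m_s, a_grid)
        asd[finite] = a
        aac[finite] = c_db
    return (
        assemble_parametric_image(blocks, asd, "ASD", step_mm),
        assemble_parametric_image(blocks, aac, "AAC", step_mm),
    )
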