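"""Patient-level QUS feature construction.

The canonical feature grid is
``{MBF, SS, SI, ASD, AAC} x {core, margin} x {MEAN, CON, COR, ENE, HOM}``
plus a core-to-margin ratio (CMR) and contrast ratio (CMCR) per parameter
and the single ACE value — 61 QUS features per patient, averaged over the
4-7 image planes covering the tumour.  Optional molecular markers (ER, PR,
HER2 as 0/1) can be appended.

CMR and CMCR compare the block-value populations of the two parametric
image regions the way SNR and CNR compare signal to background:

    CMR  = mean_core / mean_margin
    CMCR = |mean_core - mean_margin| / sqrt(sd_core^2 + sd_margin^2)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backscatter import apparent_backscatter, map_backscatter
from .containers import RFFrame, ROIMask
from .roi import AnalysisBlock, ParametricImage, assemble_parametric_image, build_margin_mask, tile_blocks
from .spectral import (
    DEFAULT_BAND_MHZ,
    NormalizedSpectrum,
    block_power_spectrum,
    correct_attenuation,
    estimate_ace,
    fit_linear_spectrum,
    normalize_spectrum,
)
from .texture import DEFAULT_OFFSETS, TextureVector, texture_features

PARAMS = ("MBF", "SS", "SI", "ASD", "AAC")
REGIONS = ("core", "margin")
STATS = ("MEAN", "CON", "COR", "ENE", "HOM")
MOLECULAR = ("ER", "PR", "HER2")


def qus_feature_names() -> list[str]:
    """The canonical 61-name feature dictionary, in documented order."""
    names = [f"{p}_{r}_{s}" for p in PARAMS for r in REGIONS for s in STATS]
    names += [f"{p}_{ratio}" for p in PARAMS for ratio in ("CMR", "CMCR")]
    names.append("ACE_core_MEAN")
    return names


@dataclass
class ExtractionConfig:
    """Everything the per-plane feature extraction needs to know."""

    band_mhz: tuple[float, float] = DEFAULT_BAND_MHZ
    block_mm: float = 2.0
    overlap: float = 0.8
    min_inside: float = 0.5
    margin_thickness_mm: float = 5.0
    glcm_levels: int = 16
    glcm_offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    glcm_symmetric: bool = True
    window: str = "hann"
    alpha_reference_db_cm_mhz: float = 0.5
    ref_a_eff_um: float = 5.0
    ref_aac_db: float = 0.0
    min_depth_span_mm: float = 10.0
    a_eff_grid: tuple[float, float, float] = (1.0, 150.0, 1.0)
    #: Overlying tissue path for attenuation compensation: "surface" uses the
    #: full depth from the transducer face (correct when the ACE describes
    #: the whole overlying medium, as for homogeneous phantoms); "roi_top"
    #: compensates only the path below the ROI's shallowest row (leaves a
    #: constant per-patient tilt when tissue above the ROI differs).
    path_mode: str = "surface"

    @property
    def step_mm(self) -> float:
        return self.block_mm * (1.0 - self.overlap)


def region_stats(
    image: ParametricImage,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> tuple[float, float, TextureVector]:
    """Mean, sample SD and Haralick textures over an image's valid cells."""
    vals = image.valid_values
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn(f"empty region for {image.name}; statistics missing", stacklevel=2)
        return math.nan, math.nan, TextureVector(math.nan, math.nan, math.nan, math.nan)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else math.nan
    textures = texture_features(image, levels=levels, offsets=offsets, symmetric=symmetric)
    return mean, sd, textures


def cmr(core_mean: float, margin_mean: float) -> float:
    """Core-to-margin ratio of region means; undefined for a zero margin."""
    if not np.isfinite(core_mean) or not np.isfinite(margin_mean) or margin_mean == 0:
        return math.nan
    return core_mean / margin_mean


def cmcr(core_mean: float, core_sd: float, margin_mean: float, margin_sd: float) -> float:
    """CNR-style core-to-margin contrast ratio.

    Invariant under common positive rescaling of the parameter (not under
    shifts); undefined when both regions are perfectly uniform.
    """
    if not all(np.isfinite(v) for v in (core_mean, core_sd, margin_mean, margin_sd)):
        return math.nan
    denom = math.hypot(core_sd, margin_sd)
    if denom == 0:
        return math.nan
    return abs(core_mean - margin_mean) / denom


def aggregate_patient(plane_features: list[dict[str, float]]) -> dict[str, float]:
    """Unweighted mean across image planes, missing-aware per feature."""
    if not plane_features:
        raise ValueError("at least one image plane is required")
    keys: list[str] = []
    for plane in plane_features:
        for k in plane:
            if k not in keys:
                keys.append(k)
    out: dict[str, float] = {}
    for k in keys:
        vals = [p[k] for p in plane_features if k in p and np.isfinite(p[k])]
        out[k] = float(np.mean(vals)) if vals else math.nan
    return out


def build_feature_matrix(
    patients: dict[str, dict[str, float]],
    include_molecular: bool = False,
    molecular: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble per-patient feature dicts into the canonical FeatureTable.

    Columns follow :func:`qus_feature_names`; with ``include_molecular``,
    ER/PR/HER2 columns (0/1, NA allowed) are appended from ``molecular``
    (indexed by patient id, lower-case column names accepted).
    """
    ids = list(patients)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    columns = qus_feature_names()
    table = pd.DataFrame(
        [[patients[pid].get(c, math.nan) for c in columns] for pid in ids],
        index=pd.Index(ids, name="patient_id"),
        columns=columns,
    )
    if include_molecular:
        if molecular is None:
            raise ValueError("include_molecular requires a molecular marker table")
        lookup = {c.lower(): c for c in molecular.columns}
        for marker in MOLECULAR:
            src = lookup.get(marker.lower())
            if src is None:
                raise ValueError(f"molecular table missing column {marker}")
            table[marker] = molecular.loc[table.index, src].astype(float).to_numpy()
    return table


def _reference_row_spectra(
    reference: RFFrame, rows: list[int], n_axial: int, window: str
) -> dict[int, np.ndarray]:
    """Reference-phantom periodograms per block depth, averaged across the
    full lateral aperture (the standard variance-reduction trick)."""
    out: dict[int, np.ndarray] = {}
    for r0 in rows:
        block = AnalysisBlock(
            sample_start=r0,
            line_start=0,
            n_samples_axial=n_axial,
            n_lines=reference.n_lines,
            depth_mm=float(reference.depth_mm(r0 + n_axial / 2.0)),
            region="reference",
        )
        _, out[r0] = block_power_spectrum(reference, block, window=window)
    return out


def extract_plane_features(
    frame: RFFrame,
    reference: RFFrame,
    core: ROIMask,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Run the full QUS chain on one image plane and return its 61 features.

    Pipeline per plane: margin ring -> block tiling (core and margin,
    exclusive assignment) -> ACE by the spectral difference method on the
    core -> per-block normalized, attenuation-corrected spectra -> linear
    spectral fits and backscatter-model fits -> parametric images ->
    region means/SDs/textures, CMR/CMCR per parameter, and the ACE itself.
    """
    cfg = config or ExtractionConfig()
    margin = build_margin_mask(core, cfg.margin_thickness_mm, frame.pixel_dims_mm)

    blocks = {
        "core": tile_blocks(
            core, frame, block_mm=cfg.block_mm, overlap=cfg.overlap, min_inside=cfg.min_inside
        ),
        "margin": tile_blocks(
            margin,
            frame,
            block_mm=cfg.block_mm,
            overlap=cfg.overlap,
            min_inside=cfg.min_inside,
            exclude=core,
        ),
    }
    if not blocks["core"]:
        raise ValueError("tumour core too small for any analysis block")

    ace = estimate_ace(
        frame,
        core,
        reference,
        alpha_reference_db_cm_mhz=cfg.alpha_reference_db_cm_mhz,
        band_mhz=cfg.band_mhz,
        block_mm=cfg.block_mm,
        overlap=cfg.overlap,
        window=cfg.window,
        min_depth_span_mm=cfg.min_depth_span_mm,
    )

    core_rows = np.array([b.sample_start for b in blocks["core"]])
    roi_top_mm = float(frame.depth_mm(int(core_rows.min())))

    features: dict[str, float] = {}
    stats_by_region: dict[str, dict[str, tuple[float, float]]] = {}
    for region, region_blocks in blocks.items():
        if not region_blocks:
            warnings.warn(f"no analysis blocks in the {region} region", stacklevel=2)
            stats_by_region[region] = {p: (math.nan, math.nan) for p in PARAMS}
            for p in PARAMS:
                for s in STATS:
                    features[f"{p}_{region}_{s}"] = math.nan
            continue
        n_axial = region_blocks[0].n_samples_axial
        ref_spectra = _reference_row_spectra(
            reference, sorted({b.sample_start for b in region_blocks}), n_axial, cfg.window
        )
        corrected: list[NormalizedSpectrum] = []
        fits = []
        for b in region_blocks:
            freq, power = block_power_spectrum(frame, b, window=cfg.window)
            if cfg.path_mode == "surface":
                path_mm = max(b.depth_mm - frame.axial_origin_mm, 0.0)
            elif cfg.path_mode == "roi_top":
                path_mm = max(b.depth_mm - roi_top_mm, 0.0)
            else:
                raise ValueError(f"unknown path_mode {cfg.path_mode!r}")
            spec = normalize_spectrum(
                power,
                ref_spectra[b.sample_start],
                freq,
                band_mhz=cfg.band_mhz,
                depth_mm=b.depth_mm,
                path_mm=path_mm,
            )
            spec = correct_attenuation(
                spec, ace.ace_db_cm_mhz, cfg.alpha_reference_db_cm_mhz
            )
            corrected.append(spec)
            fits.append(fit_linear_spectrum(spec))

        images: dict[str, ParametricImage] = {
            "MBF": assemble_parametric_image(
                region_blocks, np.array([f.mbf_db for f in fits]), "MBF", cfg.step_mm
            ),
            "SS": assemble_parametric_image(
                region_blocks, np.array([f.ss_db_mhz for f in fits]), "SS", cfg.step_mm
            ),
            "SI": assemble_parametric_image(
                region_blocks, np.array([f.si_db for f in fits]), "SI", cfg.step_mm
            ),
        }
        asd_img, aac_img = map_backscatter(
            region_blocks,
            corrected,
            c_m_s=frame.speed_of_sound_m_s,
            ref_a_eff_um=cfg.ref_a_eff_um,
            ref_aac_db=cfg.ref_aac_db,
            a_grid=cfg.a_eff_grid,
            step_mm=cfg.step_mm,
        )
        images["ASD"] = asd_img
        images["AAC"] = aac_img

        stats_by_region[region] = {}
        for p in PARAMS:
            mean, sd, tex = region_stats(
                images[p],
                levels=cfg.glcm_levels,
                offsets=cfg.glcm_offsets,
                symmetric=cfg.glcm_symmetric,
            )
            stats_by_region[region][p] = (mean, sd)
            features[f"{p}_{region}_MEAN"] = mean
            for s, v in tex.as_dict().items():
                features[f"{p}_{region}_{s}"] = v

    for p in PARAMS:
        c_mean, c_sd = stats_by_region["core"][p]
        m_mean, m_sd = stats_by_region["margin"][p]
        features[f"{p}_CMR"] = cmr(c_mean, m_mean)
        features[f"{p}_CMCR"] = cmcr(c_mean, c_sd, m_mean, m_sd)
    features["ACE_core_MEAN"] = ace.ace_db_cm_mhz
    return features
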