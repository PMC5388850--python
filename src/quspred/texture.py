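"""GLCM-based Haralick textures (CON, COR, ENE, HOM) on parametric images.

Textures are computed on the block-grid parametric image — the native
resolution of the QUS estimates — with invalid lattice nodes excluded: a
pixel pair contributes only when both members are valid.  Counts from all
offsets are pooled into one symmetric co-occurrence matrix before
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import ParametricImage

#: Distance-1 offsets at 0, 90, 45 and 135 degrees (row, col).
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


class DegenerateRegionError(ValueError):
    """The region has too little variation (or too few pairs) for texture."""


@dataclass
class GLCM:
    """Normalized gray-level co-occurrence matrix p(i, j), sum = 1."""

    p: np.ndarray
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(self.p < 0):
            raise ValueError("GLCM entries must be non-negative")

    @property
    def levels(self) -> int:
        return self.p.shape[0]


@dataclass
class TextureVector:
    """The four Haralick features used throughout this package."""

    con: float
    cor: float
    ene: float
    hom: float

    def as_dict(self) -> dict[str, float]:
        return {"CON": self.con, "COR": self.cor, "ENE": self.ene, "HOM": self.hom}


#: Texture vector reported for regions with no gray-level variation:
#: a constant region has zero contrast, maximal energy/homogeneity, and
#: an undefined correlation (recorded as missing).
DEGENERATE_TEXTURES = TextureVector(con=0.0, cor=float("nan"), ene=1.0, hom=1.0)


def quantize(image: ParametricImage, levels: int = 16) -> np.ndarray:
    """Linear min-max binning of valid cells into ``levels`` gray levels.

    Returns an integer image with invalid cells set to -1.  Quantization is
    invariant to affine rescaling of the parameter values.  A region with
    fewer than two distinct values cannot be binned and raises
    :class:`DegenerateRegionError`.
    """
    if levels < 2:
        raise ValueError("need at least two gray levels")
    vals = image.valid_values
    finite = vals[np.isfinite(vals)]
    if finite.size < 2 or np.ptp(finite) == 0:
        raise DegenerateRegionError("constant or empty region cannot be quantized")
    lo, hi = finite.min(), finite.max()
    out = np.full(image.values.shape, -1, dtype=int)
    scaled = (image.values[image.valid] - lo) / (hi - lo) * levels
    out[image.valid] = np.clip(scaled.astype(int), 0, levels - 1)
    return out


def compute_glcm(
    quantized: np.ndarray,
    levels: int,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCM:
    """Pooled co-occurrence matrix over the given offsets.

    A pair (p, p + offset) is counted only when both pixels are valid
    (value >= 0).  With ``symmetric`` each pair is counted in both
    directions before normalization to a sum of one.
    """
    quantized = np.asarray(quantized)
    counts = np.zeros((levels, levels), dtype=np.int64)
    rows, cols = quantized.shape if quantized.ndim == 2 else (0, 0)
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = rows - max(0, dr)
        c0 = max(0, -dc)
        c1 = cols - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        a = quantized[r0:r1, c0:c1]
        b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            np.add.at(counts, (a[ok], b[ok]), 1)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateRegionError("no valid pixel pairs for any offset")
    return GLCM(p=counts / total, offsets=tuple(offsets), symmetric=symmetric)


def haralick(glcm: GLCM) -> TextureVector:
    """Contrast, correlation, energy and homogeneity of a GLCM.

    COR is undefined (NaN) when either marginal standard deviation
    vanishes, e.g. for a constant image.
    """
    p = glcm.p
    g = p.shape[0]
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    con = float(np.sum((i - j) ** 2 * p))
    ene = float(np.sum(p**2))
    hom = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i <= 0 or var_j <= 0:
        cor = float("nan")
    else:
        cor = float(np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j))
    return TextureVector(con=con, cor=cor, ene=ene, hom=hom)


def texture_features(
    image: ParametricImage,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> TextureVector:
    """Quantize, pool a GLCM, and reduce to the four Haralick features.

    Degenerate regions (constant values, or no valid neighbour pairs) map
    to the conventional limit CON=0, ENE=1, HOM=1 with COR missing.
    """
    try:
        q = quantize(image, levels)
        glcm = compute_glcm(q, levels, offsets, symmetric)
    except DegenerateRegionError:
        return DEGENERATE_TEXTURES
    return haralick(glcm)
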