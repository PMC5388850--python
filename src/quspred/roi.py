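"""ROI geometry: margin rings, overlapping analysis-block tiling, and
assembly of block-level estimates into parametric images.

All physical sizes are in mm; masks live on the rectilinear B-mode/RF grid
with row = axial and col = lateral (0-based, half-open extents).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import ROIMask  # re-exported for callers

__all__ = [
    "AnalysisBlock",
    "ParametricImage",
    "ROIMask",
    "build_margin_mask",
    "tile_blocks",
    "assemble_parametric_image",
]


@dataclass(frozen=True)
class AnalysisBlock:
    """One sliding-window analysis block, in sample/line coordinates.

    ``grid_row``/``grid_col`` are the block's indices on the tiling lattice,
    used to place its parameter estimates into a parametric image.
    """

    sample_start: int
    line_start: int
    n_samples_axial: int
    n_lines: int
    depth_mm: float
    region: str = "core"
    grid_row: int = 0
    grid_col: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_axial <= 0 or self.n_lines <= 0:
            raise ValueError("block size must be positive")


@dataclass
class ParametricImage:
    """Parameter values on the block-tiling lattice.

    ``values`` holds one entry per lattice node; nodes never covered by a
    block are invalid (NaN, ``valid`` False) and excluded from statistics.
    """

    values: np.ndarray
    valid: np.ndarray
    name: str
    step_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must have the same shape")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def build_margin_mask(
    core: ROIMask, thickness_mm: float, pixel_dims_mm: tuple[float, float]
) -> ROIMask:
    """Ring of tissue around the tumour core.

    The margin contains every pixel whose Euclidean distance (in physical
    mm, anisotropic pixels supported) to the nearest core pixel lies in
    ``(0, thickness_mm]``.  It is disjoint from the core by construction
    and clipped at the frame edges.
    """
    if thickness_mm <= 0:
        raise ValueError("margin thickness must be positive")
    if not core.mask.any():
        raise ValueError("core mask is empty")
    # Distance from each non-core pixel to the nearest core pixel, in mm.
    dist = ndimage.distance_transform_edt(~core.mask, sampling=pixel_dims_mm)
    margin = (dist > 0) & (dist <= thickness_mm)
    if not margin.any():
        raise ValueError(
            "margin is empty (core touches every frame edge or thickness below pixel size)"
        )
    return ROIMask(mask=margin, region="margin")


def tile_blocks(
    mask: ROIMask,
    frame,
    block_mm: float = 2.0,
    overlap: float = 0.8,
    min_inside: float = 0.5,
    region: str | None = None,
    exclude: ROIMask | None = None,
) -> list[AnalysisBlock]:
    """Tile a region with square analysis blocks on a sliding lattice.

    The lattice is anchored at the mask's bounding box and advances by
    ``block_mm * (1 - overlap)`` (0.4 mm for the 2 mm / 80 % defaults) in
    both directions; a block is kept when at least ``min_inside`` of its
    area lies inside the mask.  When ``exclude`` is given (e.g. the core
    while tiling the margin), a candidate also satisfying ``min_inside``
    on the excluded mask is assigned there instead and dropped here, so
    every block belongs to exactly one region (ties go to the core).
    Ordering is deterministic (axial-major).
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    if block_mm <= 0:
        raise ValueError("block size must be positive")
    if not (0 < min_inside <= 1):
        raise ValueError("min_inside must lie in (0, 1]")
    region = region or mask.region
    ax_mm, lat_mm = frame.pixel_dims_mm
    if mask.mask.shape != frame.samples.shape:
        raise ValueError("mask shape does not match the RF frame grid")
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        warnings.warn("mask is empty; no analysis blocks tiled", stacklevel=2)
        return []
    n_ax = max(int(round(block_mm / ax_mm)), 1)
    n_lat = max(int(round(block_mm / lat_mm)), 1)
    if n_ax > frame.n_samples or n_lat > frame.n_lines:
        raise ValueError("analysis block does not fit inside the frame")
    step_mm = block_mm * (1.0 - overlap)

    # Integral images for O(1) in-mask pixel counts per candidate block.
    def make_integral(m: np.ndarray) -> np.ndarray:
        integral = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
        integral[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
        return integral

    integral = make_integral(mask.mask)
    integral_ex = make_integral(exclude.mask) if exclude is not None else None

    def count(ii: np.ndarray, r0: int, c0: int) -> int:
        r1, c1 = r0 + n_ax, c0 + n_lat
        return int(ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0])

    bbox_r0_mm, bbox_r1_mm = rows.min() * ax_mm, (rows.max() + 1) * ax_mm
    bbox_c0_mm, bbox_c1_mm = cols.min() * lat_mm, (cols.max() + 1) * lat_mm
    tol = 1e-9
    ax_starts_mm = np.arange(bbox_r0_mm, bbox_r1_mm - block_mm * min_inside + tol, step_mm)
    lat_starts_mm = np.arange(bbox_c0_mm, bbox_c1_mm - block_mm * min_inside + tol, step_mm)
    if ax_starts_mm.size == 0 or lat_starts_mm.size == 0:
        warnings.warn("mask smaller than one analysis block; nothing tiled", stacklevel=2)
        return []

    area = n_ax * n_lat
    blocks: list[AnalysisBlock] = []
    for i, r_mm in enumerate(ax_starts_mm):
        r0 = int(round(r_mm / ax_mm))
        if r0 + n_ax > frame.n_samples:
            continue
        for j, c_mm in enumerate(lat_starts_mm):
            c0 = int(round(c_mm / lat_mm))
            if c0 + n_lat > frame.n_lines:
                continue
            if count(integral, r0, c0) / area < min_inside - tol:
                continue
            if integral_ex is not None and count(integral_ex, r0, c0) / area >= min_inside - tol:
                continue
            blocks.append(
                    AnalysisBlock(
                        sample_start=r0,
                        line_start=c0,
                        n_samples_axial=n_ax,
                        n_lines=n_lat,
                        depth_mm=float(frame.depth_mm(r0 + n_ax / 2.0)),
                        region=region,
                        grid_row=i,
                        grid_col=j,
                    )
                )
    if not blocks:
        warnings.warn("no analysis block reached the min_inside coverage", stacklevel=2)
    return blocks


def assemble_parametric_image(
    blocks: list[AnalysisBlock],
    values: np.ndarray,
    name: str,
    step_mm: float = 0.4,
) -> ParametricImage:
    """Place per-block parameter values at their lattice nodes.

    Lattice nodes not covered by any block stay invalid and are excluded
    from every downstream statistic and texture computation.
    """
    values = np.asarray(values, dtype=float)
    if len(blocks) != values.size:
        raise ValueError(f"{len(blocks)} blocks but {values.size} values")
    if not blocks:
        return ParametricImage(
            values=np.empty((0, 0)), valid=np.empty((0, 0), dtype=bool), name=name, step_mm=step_mm
        )
    n_rows = max(b.grid_row for b in blocks) + 1
    n_cols = max(b.grid_col for b in blocks) + 1
    grid = np.full((n_rows, n_cols), np.nan)
    valid = np.zeros((n_rows, n_cols), dtype=bool)
    for b, v in zip(blocks, values.ravel()):
        grid[b.grid_row, b.grid_col] = v
        valid[b.grid_row, b.grid_col] = np.isfinite(v)
    return ParametricImage(values=grid, valid=valid, name=name, step_mm=step_mm)
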