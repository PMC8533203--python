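"""The 2D binary Poincare plot and its geometric features.

RR couples (RR(n), RR(n+1)) are binned on a square millisecond grid into a
binary occupancy image.  Two binary-morphology operators clean the raster:
an *area opening* removes salt-and-pepper components smaller than a pixel
threshold, and a *hole fill* turns background regions not connected to the
image border into foreground.  Scanning the cleaned plot column by column
with a vertical line yields the variability-extension (VE) curve — scatter
width as a function of RR — from which four features are read:

=========  ====================================================
L [ms]     horizontal length of the plot (outermost column edges)
HVE [ms]   highest variability extension, max of the VE curve at RR*
A [ms^2]   area, foreground pixel count times pixel area
P [%]      position of RR* along L, from the left edge of support
=========  ====================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import morphology

from .rr_io import RRPairs

__all__ = [
    "GridSpec",
    "PlotImage2D",
    "VECurve",
    "Features2D",
    "rasterize",
    "area_open",
    "fill_holes",
    "compute_ve",
    "features_2d",
    "pipeline_2d",
]


@dataclass(frozen=True)
class GridSpec:
    """Square binning grid shared by the 2D and 3D plots.

    ``bin_width_ms`` defaults to 8 ms, close to the 7.8 ms RR quantisation of
    a 128 Hz Holter recorder.  Bin ``c`` covers the half-open interval
    ``[origin + c*w, origin + (c+1)*w)``.  ``connectivity`` is the foreground
    pixel-neighbourhood (8 by default); hole filling uses the complementary
    connectivity for the background.
    """

    bin_width_ms: float = 8.0
    origin_ms: float = 0.0
    connectivity: int = 8

    def __post_init__(self):
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def bin_of(self, v_ms):
        return np.floor((np.asarray(v_ms, dtype=float) - self.origin_ms)
                        / self.bin_width_ms).astype(np.int64)

    def center_of(self, bin_index):
        return self.origin_ms + (np.asarray(bin_index, dtype=float) + 0.5) * self.bin_width_ms

    def left_edge_of(self, bin_index):
        return self.origin_ms + np.asarray(bin_index, dtype=float) * self.bin_width_ms

    @property
    def skimage_connectivity(self) -> int:
        # skimage/ndimage express 2D connectivity as 1 (4-neigh) or 2 (8-neigh)
        return 2 if self.connectivity == 8 else 1


@dataclass(frozen=True)
class PlotImage2D:
    """Binary occupancy raster of the Poincare plot.

    ``occupancy[row, col]`` is True when at least one RR couple fell in the
    bin; ``x0``/``y0`` are the global bin indices of column 0 / row 0, so the
    stored array is the occupied bounding box plus a one-pixel margin.
    ``provenance`` tracks the cleanup stage: raw -> opened -> filled.
    """

    grid: GridSpec
    occupancy: np.ndarray
    x0: int
    y0: int
    provenance: str

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return self.occupancy.size == 0 or not self.occupancy.any()

    def occupied_columns(self) -> np.ndarray:
        """Global x-bin indices of columns containing foreground."""
        return np.flatnonzero(self.occupancy.any(axis=0)) + self.x0


def _require(img: PlotImage2D, stage: str, op: str) -> None:
    if img.provenance != stage:
        raise ValueError(
            f"{op} expects a {stage!r}-stage image, got {img.provenance!r}"
        )


def rasterize(pairs: RRPairs, grid: GridSpec | None = None) -> PlotImage2D:
    """Bin RR couples into a binary image (half-open bins, 1-pixel margin)."""
    grid = grid or GridSpec()
    if len(pairs) == 0:
        warnings.warn("rasterize: empty pair set -> empty image", stacklevel=2)
        return PlotImage2D(grid, np.zeros((0, 0), dtype=bool), 0, 0, "raw")
    if np.any(pairs.x < grid.origin_ms) or np.any(pairs.y < grid.origin_ms):
        raise ValueError("pair values below the grid origin")
    xb = grid.bin_of(pairs.x)
    yb = grid.bin_of(pairs.y)
    x0 = int(xb.min()) - 1
    y0 = int(yb.min()) - 1
    occ = np.zeros((int(yb.max()) - y0 + 2, int(xb.max()) - x0 + 2), dtype=bool)
    occ[yb - y0, xb - x0] = True
    return PlotImage2D(grid, occ, x0, y0, "raw")


def area_open(img: PlotImage2D, min_pixels: int = 4) -> PlotImage2D:
    """Remove connected components with fewer than ``min_pixels`` pixels."""
    _require(img, "raw", "area_open")
    if img.is_empty:
        return replace(img, provenance="opened")
    # max_size is inclusive: removes components of size <= min_pixels - 1
    opened = morphology.remove_small_objects(
        img.occupancy, max_size=min_pixels - 1,
        connectivity=img.grid.skimage_connectivity,
    )
    return replace(img, occupancy=opened, provenance="opened")


def fill_holes(img: PlotImage2D) -> PlotImage2D:
    """Fill background regions not connected to the image border.

    The background is traversed under the connectivity complementary to the
    foreground's (4-neighbourhood when the foreground uses 8), the standard
    duality that keeps a diagonal foreground chain hole-tight.
    """
    _require(img, "opened", "fill_holes")
    if img.is_empty:
        return replace(img, provenance="filled")
    bg_conn = 1 if img.grid.connectivity == 8 else 2
    structure = ndimage.generate_binary_structure(2, bg_conn)
    filled = ndimage.binary_fill_holes(img.occupancy, structure=structure)
    return replace(img, occupancy=filled, provenance="filled")


@dataclass(frozen=True)
class VECurve:
    """Scatter width (ms) per occupied column; RR* locates the maximum."""

    columns: np.ndarray   # global x-bin indices with foreground
    ve_ms: np.ndarray     # vertical extent per column, ms
    rr_star_ms: float     # bin center of the lowest-RR column achieving max

    @property
    def hve_ms(self) -> float:
        return float(self.ve_ms.max())


def compute_ve(img: PlotImage2D) -> VECurve:
    """Scan the cleaned plot with a vertical line, column by column.

    A column's VE is its vertical extent ``(max_row - min_row + 1) * w`` —
    a width reading that spans residual interior gaps.  Ties for the maximum
    resolve to the lowest-RR column.
    """
    if img.is_empty:
        raise ValueError("compute_ve: no foreground after cleanup")
    _require(img, "filled", "compute_ve")
    occ = img.occupancy
    any_col = occ.any(axis=0)
    cols = np.flatnonzero(any_col)
    rows_min = np.argmax(occ[:, cols], axis=0)
    rows_max = occ.shape[0] - 1 - np.argmax(occ[::-1, cols], axis=0)
    ve = (rows_max - rows_min + 1).astype(float) * img.grid.bin_width_ms
    best = cols[int(np.argmax(ve))]  # argmax returns the first (lowest) column
    rr_star = float(img.grid.center_of(best + img.x0))
    return VECurve(columns=cols + img.x0, ve_ms=ve, rr_star_ms=rr_star)


@dataclass(frozen=True)
class Features2D:
    L_ms: float
    HVE_ms: float
    A_ms2: float
    P_pct: float
    rr_star_ms: float


def features_2d(img: PlotImage2D, ve: VECurve) -> Features2D:
    """Assemble L, HVE, A and P from a cleaned image and its VE curve."""
    if img.is_empty:
        raise ValueError("features_2d: empty image")
    _require(img, "filled", "features_2d")
    w = img.grid.bin_width_ms
    cols = img.occupied_columns()
    c_min, c_max = int(cols.min()), int(cols.max())
    left_edge = float(img.grid.left_edge_of(c_min))
    L = (c_max + 1 - c_min) * w
    A = img.n_foreground * w * w
    P = 100.0 * (ve.rr_star_ms - left_edge) / L
    return Features2D(
        L_ms=float(L),
        HVE_ms=ve.hve_ms,
        A_ms2=float(A),
        P_pct=float(np.clip(P, 0.0, 100.0)),
        rr_star_ms=ve.rr_star_ms,
    )


def pipeline_2d(
    pairs: RRPairs,
    grid: GridSpec | None = None,
    min_pixels: int = 4,
    fill: bool = True,
    ve_on_filled: bool = True,
) -> tuple[PlotImage2D, VECurve, Features2D]:
    """rasterize -> area_open -> fill_holes -> VE -> features, in one call.

    ``ve_on_filled=False`` computes the VE curve (and features) on the opened
    image instead of the hole-filled one.
    """
    grid = grid or GridSpec()
    opened = area_open(rasterize(pairs, grid), min_pixels=min_pixels)
    filled = fill_holes(opened) if fill else replace(opened, provenance="filled")
    target = filled if ve_on_filled else replace(opened, provenance="filled")
    ve = compute_ve(target)
    return target, ve, features_2d(target, ve)
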