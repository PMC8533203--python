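"""The 3D Poincare plot: occurrence histogram, peaks, and inertia radii.

Binning the same RR couples on the same grid but *counting* occurrences per
bin turns the scatter into a surface — the 3D Poincare plot.  Three kinds of
descriptors are taken from it:

* ``Np`` — the number of peaks: connected equal-height plateaus that are
  regional maxima, kept when their height reaches a threshold expressed as a
  fraction of the global maximum (0.5 by default, where the peak count
  stabilises — lower thresholds overestimate, higher ones underestimate).
* ``Dp`` [ms] — the mean distance of those peaks from the axis of symmetry,
  the identity line RR(n+1) = RR(n).
* ``rho_x``, ``rho_y`` [ms] and ``rho_z`` [adim] — per-axis radii of inertia
  of the semi-ellipsoid of inertia, treating each occupied bin as a unit
  point mass at (x-center, y-center, count): the RMS spread of the N points
  about their barycenter (Xg, Yg, Zg) along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import ndimage
from skimage import morphology

from .plot2d import GridSpec
from .rr_io import RRPairs

__all__ = [
    "Histogram3D",
    "PeakSet",
    "InertiaSummary",
    "Features3D",
    "histogram3d",
    "detect_peaks",
    "mean_peak_distance",
    "inertia_radii",
    "features_3d",
    "pipeline_3d",
]


@dataclass(frozen=True)
class Histogram3D:
    """Occurrence counts of RR couples over the (x-bin, y-bin) grid."""

    grid: GridSpec
    counts: np.ndarray  # 2D int array, [row, col]
    x0: int             # global bin index of column 0
    y0: int             # global bin index of row 0

    @property
    def n_points(self) -> int:
        """Number of occupied bins — the N point masses of the 3D plot."""
        return int(np.count_nonzero(self.counts))

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks as (x_ms, y_ms, height) triples, plateau-merged."""

    peaks: tuple
    threshold: float

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class InertiaSummary:
    Xg_ms: float
    Yg_ms: float
    Zg: float
    rho_x_ms: float
    rho_y_ms: float
    rho_z: float


@dataclass(frozen=True)
class Features3D:
    Np: int
    Dp_ms: float
    rho_x_ms: float
    rho_y_ms: float
    rho_z: float


def histogram3d(pairs: RRPairs, grid: GridSpec | None = None) -> Histogram3D:
    """Tally RR couples per bin under the same half-open convention as 2D."""
    grid = grid or GridSpec()
    if len(pairs) == 0:
        raise ValueError("histogram3d: empty pair set")
    xb = grid.bin_of(pairs.x)
    yb = grid.bin_of(pairs.y)
    x0, y0 = int(xb.min()), int(yb.min())
    counts = np.zeros((int(yb.max()) - y0 + 1, int(xb.max()) - x0 + 1),
                      dtype=np.int64)
    np.add.at(counts, (yb - y0, xb - x0), 1)
    return Histogram3D(grid=grid, counts=counts, x0=x0, y0=y0)


def detect_peaks(hist: Histogram3D, threshold_frac: float = 0.5) -> PeakSet:
    """Find regional-maximum plateaus at least ``threshold_frac * max`` high.

    A peak is an 8-connected plateau of equal counts strictly greater than
    every neighbouring bin outside it; each plateau contributes one peak at
    its (count-weighted, hence arithmetic) centroid.  The height comparison
    against the threshold is inclusive (>=).
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    counts = hist.counts
    if counts.size == 0 or counts.max() == 0:
        raise ValueError("detect_peaks: empty histogram")
    threshold = threshold_frac * float(counts.max())
    # pad with a zero border so plateaus touching the array edge (including a
    # completely full histogram, which is flat) are still regional maxima
    padded = np.pad(counts, 1)
    maxima = morphology.local_maxima(padded, connectivity=2, allow_borders=False)
    labeled, n_lab = ndimage.label(maxima, structure=np.ones((3, 3), dtype=int))
    peaks = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labeled == lab)
        rows, cols = rows - 1, cols - 1
        height = int(counts[rows[0], cols[0]])
        if height >= threshold:
            x_ms = float(np.mean(hist.grid.center_of(cols + hist.x0)))
            y_ms = float(np.mean(hist.grid.center_of(rows + hist.y0)))
            peaks.append((x_ms, y_ms, height))
    peaks.sort(key=lambda p: (p[0], p[1]))
    return PeakSet(peaks=tuple(peaks), threshold=threshold)


def mean_peak_distance(peaks: PeakSet, convention: str = "perpendicular") -> float:
    """Mean distance of the peaks from the identity line y = x.

    ``perpendicular`` (default) uses the Euclidean point-line distance
    |x - y| / sqrt(2); ``absdiff`` uses |x - y| directly.
    """
    if len(peaks) == 0:
        raise ValueError("mean_peak_distance: empty peak set")
    d = np.array([abs(x - y) for x, y, _ in peaks.peaks], dtype=float)
    if convention == "perpendicular":
        d = d / sqrt(2.0)
    elif convention != "absdiff":
        raise ValueError(f"unknown distance convention {convention!r}")
    return float(d.mean())


def inertia_radii(hist: Histogram3D, weighted: bool = False) -> InertiaSummary:
    """Barycenter and per-axis radii of inertia of the occupied bins.

    Default model: one unit mass per occupied bin at (x-center, y-center,
    count), so radii are plain RMS spreads of the N points about their mean.
    ``weighted=True`` instead weights each bin by its count.
    """
    rows, cols = np.nonzero(hist.counts)
    if rows.size == 0:
        raise ValueError("inertia_radii: empty histogram")
    x = hist.grid.center_of(cols + hist.x0)
    y = hist.grid.center_of(rows + hist.y0)
    z = hist.counts[rows, cols].astype(float)
    w = z if weighted else np.ones_like(z)
    wsum = w.sum()
    xg, yg, zg = (np.dot(w, a) / wsum for a in (x, y, z))
    rx, ry, rz = (sqrt(np.dot(w, (a - g) ** 2) / wsum)
                  for a, g in ((x, xg), (y, yg), (z, zg)))
    return InertiaSummary(Xg_ms=float(xg), Yg_ms=float(yg), Zg=float(zg),
                          rho_x_ms=float(rx), rho_y_ms=float(ry), rho_z=float(rz))


def features_3d(hist: Histogram3D, peaks: PeakSet,
                inertia: InertiaSummary,
                distance_convention: str = "perpendicular") -> Features3D:
    """Assemble Np, Dp and the three inertia radii into one record."""
    return Features3D(
        Np=len(peaks),
        Dp_ms=mean_peak_distance(peaks, convention=distance_convention),
        rho_x_ms=inertia.rho_x_ms,
        rho_y_ms=inertia.rho_y_ms,
        rho_z=inertia.rho_z,
    )


def pipeline_3d(
    pairs: RRPairs,
    grid: GridSpec | None = None,
    threshold_frac: float = 0.5,
    distance_convention: str = "perpendicular",
    weighted_inertia: bool = False,
) -> tuple[Histogram3D, PeakSet, Features3D]:
    """histogram -> peaks -> inertia -> features, in one call."""
    hist = histogram3d(pairs, grid)
    peaks = detect_peaks(hist, threshold_frac=threshold_frac)
    inertia = inertia_radii(hist, weighted=weighted_inertia)
    return hist, peaks, features_3d(hist, peaks, inertia, distance_convention)
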