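"""End-to-end extraction of the nine Poincare-plot features per recording.

The unit consumed by the statistical and machine-learning stages is one row
of nine features per subject: L, HVE, A, P from the cleaned 2D binary plot
and Np, Dp, rho_x, rho_y, rho_z from the 3D occurrence plot, all computed on
the same label-filtered RR-pair stream.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import plot2d, plot3d, rr_io

__all__ = ["FEATURE_NAMES", "ExtractionConfig", "extract_features", "risk_from_nyha"]

#: Canonical feature order used by tables, wrappers and reports.
FEATURE_NAMES = (
    "L_ms", "HVE_ms", "A_ms2", "P_pct",
    "Np", "Dp_ms", "rho_x_ms", "rho_y_ms", "rho_z",
)


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the geometry stage (see :mod:`plot2d` / :mod:`plot3d`)."""

    grid: plot2d.GridSpec = plot2d.GridSpec()
    min_pixels: int = 4
    fill_on: bool = True
    ve_on_filled: bool = True
    threshold_frac: float = 0.5
    distance_convention: str = "perpendicular"
    weighted_inertia: bool = False


def extract_features(series: rr_io.RRSeries,
                     config: ExtractionConfig | None = None) -> dict:
    """Run the full chain on one annotated series and return the nine features.

    Chain: correct isolated ectopics -> build time-closed pairs -> 2D raster
    cleanup and VE features -> 3D histogram, peaks and inertia radii.
    """
    config = config or ExtractionConfig()
    corrected = rr_io.correct_isolated_ectopics(series)
    pairs = rr_io.build_pairs(corrected)
    if len(pairs) == 0:
        raise ValueError("no usable RR pairs; cannot extract features")
    _, _, f2 = plot2d.pipeline_2d(
        pairs, config.grid, min_pixels=config.min_pixels,
        fill=config.fill_on, ve_on_filled=config.ve_on_filled,
    )
    _, _, f3 = plot3d.pipeline_3d(
        pairs, config.grid, threshold_frac=config.threshold_frac,
        distance_convention=config.distance_convention,
        weighted_inertia=config.weighted_inertia,
    )
    return {
        "L_ms": f2.L_ms, "HVE_ms": f2.HVE_ms, "A_ms2": f2.A_ms2,
        "P_pct": f2.P_pct,
        "Np": f3.Np, "Dp_ms": f3.Dp_ms,
        "rho_x_ms": f3.rho_x_ms, "rho_y_ms": f3.rho_y_ms, "rho_z": f3.rho_z,
    }


def risk_from_nyha(nyha: int) -> str:
    """Merge NYHA functional classes into the two risk groups.

    Classes I and II form the low-risk group, class III the high-risk group
    (class IV is outside the supported range).
    """
    if nyha in (1, 2):
        return "low"
    if nyha == 3:
        return "high"
    raise ValueError(f"unsupported NYHA class {nyha!r} (expected 1, 2 or 3)")
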