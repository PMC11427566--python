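"""Volume-uniformity scoring of a split-droplet cohort.

Volumes follow the parallel-plate sandwich model of a two-plate EWOD cell:
a droplet squeezed between the plates occupies its footprint area times the
plate gap, ``V = A * gap``.  Because the gap is constant across the array,
the coefficient of variation of the volumes equals that of the footprint
areas, so uniformity needs no absolute calibration; absolute volumes in
nanolitres require the grid's pixel and physical pitch plus the gap height.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from dropletbench.segment import DropletContour
from dropletbench.synth import GridSpec

__all__ = ["UniformityReport", "volume_from_area", "uniformity_report"]


@dataclass
class UniformityReport:
    """Cohort volume statistics; ``cv_percent = 100 * sd / mean``."""

    n: int
    areas_px: np.ndarray
    volumes_nl: np.ndarray
    mean_volume_nl: float
    sd_volume_nl: float
    cv_percent: float


def volume_from_area(area_px: float, grid: GridSpec) -> float:
    """Convert a footprint area in pixels to a volume in nanolitres.

    ``V = area_px * (pitch_um / pitch_px)^2 * gap_um`` in cubic micrometres;
    1 nL = 1e6 um^3.  A 100 um x 100 um electrode footprint under a 200 um
    gap therefore holds 2 nL.
    """
    if area_px < 0:
        raise ValueError("area_px must be non-negative")
    um3 = area_px * grid.um_per_px**2 * grid.gap_um
    return um3 * 1e-6


def uniformity_report(
    contours: Sequence[DropletContour] | Iterable[float],
    grid: GridSpec,
) -> UniformityReport:
    """Volume coefficient of variation of a cohort of segmented droplets.

    Accepts either ``DropletContour`` objects or raw pixel areas.  The
    standard deviation is the sample (n-1) estimate, appropriate for the
    small cohorts typical of one split array (e.g. 16 subdroplets).
    """
    items = list(contours)
    areas = np.array(
        [c.area_px if isinstance(c, DropletContour) else float(c) for c in items], dtype=float
    )
    if len(areas) < 2:
        raise ValueError("uniformity needs at least 2 droplets")
    if np.any(areas <= 0):
        raise ValueError("all droplet areas must be positive")
    volumes = np.array([volume_from_area(a, grid) for a in areas])
    mean = float(volumes.mean())
    sd = float(volumes.std(ddof=1))
    return UniformityReport(
        n=len(areas),
        areas_px=areas,
        volumes_nl=volumes,
        mean_volume_nl=mean,
        sd_volume_nl=sd,
        cv_percent=100.0 * sd / mean,
    )
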