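"""Per-droplet cell counting and the single-cell generation rate.

A detected cell belongs to the droplet whose region contains its center
(point-in-polygon for contours, point-in-box for boxes); cells inside no
droplet are tallied as unassigned, and a cell inside several overlapping
droplets goes to the one with the nearest centroid.  Counts are reported in
the field's standard occupancy bins {0, 1, 2, >2}; the single-cell
generation rate is the percentage of droplets holding exactly one cell —
for Poisson-distributed loading with mean lambda it concentrates around
``lambda * exp(-lambda)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box as shapely_box
from shapely.strtree import STRtree

from dropletbench.detect_eval import DetBox
from dropletbench.segment import DropletContour

__all__ = ["CellCountReport", "assign_cells", "section_reports"]

BINS = ("0", "1", "2", ">2")


def _bin_of(count: int) -> str:
    return str(count) if count <= 2 else ">2"


@dataclass
class CellCountReport:
    """Per-droplet occupancy, the {0,1,2,>2} histogram, and the single-cell rate."""

    per_droplet: list[tuple[int, int]]  # (droplet_id, n_cells)
    histogram: dict[str, int]
    n_droplets: int
    n_single: int
    single_cell_rate_percent: float
    unassigned_cells: int = 0

    @classmethod
    def from_counts(cls, per_droplet: Sequence[tuple[int, int]], unassigned_cells: int = 0) -> "CellCountReport":
        hist = {b: 0 for b in BINS}
        for _, n in per_droplet:
            hist[_bin_of(n)] += 1
        n_droplets = len(per_droplet)
        n_single = hist["1"]
        rate = 100.0 * n_single / n_droplets if n_droplets else 0.0
        return cls(
            per_droplet=list(per_droplet),
            histogram=hist,
            n_droplets=n_droplets,
            n_single=n_single,
            single_cell_rate_percent=rate,
            unassigned_cells=unassigned_cells,
        )

    @classmethod
    def from_histogram(cls, histogram: dict[str, int]) -> "CellCountReport":
        """Build a report from occupancy-bin counts alone (no per-droplet detail)."""
        hist = {b: int(histogram.get(b, 0)) for b in BINS}
        per = []
        did = 1
        for b, n in hist.items():
            count = 3 if b == ">2" else int(b)
            for _ in range(n):
                per.append((did, count))
                did += 1
        n_droplets = sum(hist.values())
        rate = 100.0 * hist["1"] / n_droplets if n_droplets else 0.0
        return cls(
            per_droplet=per,
            histogram=hist,
            n_droplets=n_droplets,
            n_single=hist["1"],
            single_cell_rate_percent=rate,
        )


def _centroid(droplet: DropletContour | DetBox) -> tuple[float, float]:
    if isinstance(droplet, DetBox):
        return (droplet.cx, droplet.cy)
    return droplet.centroid


def assign_cells(
    droplets: Sequence[DropletContour | DetBox],
    cells: Sequence[DetBox | tuple[float, float]],
) -> CellCountReport:
    """Assign each cell to the droplet containing its center and count occupancy."""
    ids = []
    geoms = []
    for k, d in enumerate(droplets, start=1):
        if isinstance(d, DropletContour):
            ids.append(d.droplet_id)
            geoms.append(Polygon(d.polygon))
        else:
            ids.append(k)
            x1, y1, x2, y2 = d.to_corners()
            geoms.append(shapely_box(x1, y1, x2, y2))
    tree = STRtree(geoms) if geoms else None
    counts = {did: 0 for did in ids}
    unassigned = 0
    for cell in cells:
        if isinstance(cell, DetBox):
            x, y = cell.cx, cell.cy
        else:
            x, y = cell
        pt = Point(x, y)
        holders = []
        if tree is not None:
            for gi in tree.query(pt):
                g = geoms[int(gi)]
                # boxes include their boundary; polygon containment is strict
                if g.covers(pt) if not isinstance(droplets[int(gi)], DropletContour) else g.contains(pt):
                    holders.append(int(gi))
        if not holders:
            unassigned += 1
        elif len(holders) == 1:
            counts[ids[holders[0]]] += 1
        else:
            # overlap pathology: nearest centroid wins
            best = min(
                holders,
                key=lambda i: (np.hypot(x - _centroid(droplets[i])[0], y - _centroid(droplets[i])[1]), ids[i]),
            )
            counts[ids[best]] += 1
    return CellCountReport.from_counts([(did, counts[did]) for did in ids], unassigned_cells=unassigned)


def section_reports(
    report: CellCountReport, sections: dict[str, Sequence[int]]
) -> dict[str, CellCountReport]:
    """Split a report into named sections (e.g. top/middle/bottom of the chip).

    ``sections`` must partition the report's droplet ids exactly; per-bin
    counts of the section reports sum to the global histogram.
    """
    all_ids = [did for did, _ in report.per_droplet]
    claimed: list[int] = []
    for ids in sections.values():
        claimed.extend(ids)
    if sorted(claimed) != sorted(all_ids):
        raise ValueError("sections must partition the droplet ids exactly (no overlap, none missing)")
    counts = dict(report.per_droplet)
    return {
        name: CellCountReport.from_counts([(did, counts[did]) for did in ids])
        for name, ids in sections.items()
    }
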