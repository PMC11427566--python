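"""Seeded generator of droplet-array scenes with exhaustive ground truth.

Scenes emulate a camera view of droplets sitting on an active-matrix
electrode grid: disc-like droplets of roughly one-electrode footprint over a
periodic grid-line background, with per-droplet cell counts drawn from a
Poisson distribution, then optical blur and sensor noise.

Coordinate convention (shared by every module): pixel coordinates with the
origin at the top-left, x rightward, y downward.  Pixel ``(row i, col j)``
covers the half-open square ``[j, j+1) x [i, i+1)`` so its center is
``(j + 0.5, i + 0.5)``.  Boxes and centroids live in these continuous
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from dropletbench.detect_eval import DetBox

__all__ = [
    "GridSpec",
    "SceneSpec",
    "DropletTruth",
    "SceneTruth",
    "arrange_lattice",
    "render_scene",
]


@dataclass(frozen=True)
class GridSpec:
    """Electrode-grid geometry of the chip and its image.

    Parameters
    ----------
    n_cols, n_rows:
        Electrode counts along x and y.  The rendered image has shape
        ``(n_rows * pitch_px, n_cols * pitch_px)``.
    pitch_px:
        Electrode pitch in pixels (camera sampling of one electrode).
    pitch_um:
        Electrode pitch in micrometres (physical calibration).
    gap_um:
        Plate gap height in micrometres; with the parallel-plate model the
        droplet volume is footprint area times this gap.
    """

    n_cols: int
    n_rows: int
    pitch_px: int = 16
    pitch_um: float = 100.0
    gap_um: float = 200.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid needs at least one electrode per axis")
        if self.pitch_px < 4:
            raise ValueError("pitch_px must be >= 4")
        if self.pitch_um <= 0 or self.gap_um <= 0:
            raise ValueError("physical pitch and gap must be positive")

    @property
    def width_px(self) -> int:
        return self.n_cols * self.pitch_px

    @property
    def height_px(self) -> int:
        return self.n_rows * self.pitch_px

    def electrode_center_px(self, col: int, row: int) -> tuple[float, float]:
        """Continuous pixel coordinates of the center of electrode (col, row)."""
        return ((col + 0.5) * self.pitch_px, (row + 0.5) * self.pitch_px)

    @property
    def um_per_px(self) -> float:
        return self.pitch_um / self.pitch_px


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene.

    ``merged_ids`` marks droplets rendered as failed splits: their disc gets
    double the nominal area (radius scaled by sqrt(2)), emulating two
    subdroplets that never separated.
    """

    grid: GridSpec
    droplet_centers: tuple[tuple[float, float], ...]
    droplet_radius_mean_px: float = 7.0
    droplet_radius_cv: float = 0.03
    cell_rate_lambda: float = 1.3
    cell_radius_px: float = 1.5
    brightness: tuple[float, float] = (0.25, 0.85)  # (background, droplet interior)
    blur_sigma_px: float = 1.0
    noise_sigma: float = 0.02
    seed: int = 0
    allow_contact: bool = False
    merged_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.droplet_radius_mean_px <= 0:
            raise ValueError("droplet_radius_mean_px must be positive")
        if self.droplet_radius_cv < 0 or self.cell_rate_lambda < 0:
            raise ValueError("droplet_radius_cv and cell_rate_lambda must be >= 0")
        if self.blur_sigma_px < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma_px and noise_sigma must be >= 0")
        w, h = self.grid.width_px, self.grid.height_px
        for k, (x, y) in enumerate(self.droplet_centers):
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"droplet center {k} at ({x}, {y}) lies outside the image")
        bad = [i for i in self.merged_ids if not 1 <= i <= len(self.droplet_centers)]
        if bad:
            raise ValueError(f"merged_ids refer to unknown droplets: {bad}")


@dataclass(frozen=True)
class DropletTruth:
    droplet_id: int
    center: tuple[float, float]
    radius: float
    area_px: int


@dataclass(frozen=True)
class SceneTruth:
    """A rendered scene plus exhaustive ground truth."""

    image: np.ndarray  # float intensities in [0, 1]
    label_mask: np.ndarray  # int, 0 = background, k = droplet k
    droplets: tuple[DropletTruth, ...]
    cells: tuple[tuple[int | None, float, float], ...]  # (droplet_id, x, y)
    gt_boxes: tuple[DetBox, ...]

    def cell_counts(self) -> dict[int, int]:
        """Ground-truth number of cells per droplet id."""
        counts = {d.droplet_id: 0 for d in self.droplets}
        for did, _, _ in self.cells:
            if did is not None:
                counts[did] += 1
        return counts


def arrange_lattice(
    grid: GridSpec,
    n_x: int,
    n_y: int,
    spacing_electrodes: int = 4,
    origin_electrode: tuple[int, int] = (1, 1),
) -> list[tuple[float, float]]:
    """Centers (px) of an ``n_x x n_y`` droplet lattice spaced by ``spacing_electrodes``.

    Neighbouring droplets sit ``spacing_electrodes`` empty electrodes apart,
    i.e. their centers are ``(spacing_electrodes + 1) * pitch_px`` pixels
    apart.  Centers are returned in row-major order (rows of constant y).
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("lattice dimensions must be >= 1")
    if spacing_electrodes < 0:
        raise ValueError("spacing_electrodes must be >= 0")
    c0, r0 = origin_electrode
    step = spacing_electrodes + 1
    last_col = c0 + (n_x - 1) * step
    last_row = r0 + (n_y - 1) * step
    if c0 < 0 or r0 < 0 or last_col >= grid.n_cols or last_row >= grid.n_rows:
        raise ValueError(
            f"lattice exceeds grid bounds: needs electrodes up to ({last_col}, {last_row}) "
            f"on a {grid.n_cols} x {grid.n_rows} grid"
        )
    centers = []
    for j in range(n_y):
        for i in range(n_x):
            centers.append(grid.electrode_center_px(c0 + i * step, r0 + j * step))
    return centers


def _realized_radii(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n = len(spec.droplet_centers)
    mean = spec.droplet_radius_mean_px
    if spec.droplet_radius_cv == 0:
        radii = np.full(n, mean)
    else:
        radii = rng.normal(mean, spec.droplet_radius_cv * mean, size=n)
    for i in spec.merged_ids:
        radii[i - 1] *= np.sqrt(2.0)  # double footprint area: a failed (merged) split
    if np.any(radii <= 0):
        raise ValueError("realized droplet radii must be positive; lower droplet_radius_cv")
    return radii


def _check_contacts(spec: SceneSpec, radii: np.ndarray) -> None:
    centers = np.asarray(spec.droplet_centers, dtype=float)
    if len(centers) < 2:
        return
    tree = cKDTree(centers)
    for i, j in sorted(tree.query_pairs(2 * float(radii.max()) + 1.0)):
        d = float(np.hypot(*(centers[i] - centers[j])))
        if d < radii[i] + radii[j] + 1.0:
            raise ValueError(
                f"droplets {i + 1} and {j + 1} touch or overlap "
                f"(center distance {d:.2f} < {radii[i] + radii[j] + 1.0:.2f}); "
                "pass allow_contact=True to render anyway"
            )


def _paint_disc(canvas: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    h, w = canvas.shape
    j0, j1 = max(int(cx - r - 2), 0), min(int(cx + r + 3), w)
    i0, i1 = max(int(cy - r - 2), 0), min(int(cy + r + 3), h)
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    inside = (jj + 0.5 - cx) ** 2 + (ii + 0.5 - cy) ** 2 <= r**2
    canvas[i0:i1, j0:j1][inside] = value


def render_scene(spec: SceneSpec) -> SceneTruth:
    """Render a scene and its exhaustive ground truth.

    Deterministic for a fixed ``spec.seed``: radii, per-droplet cell counts,
    cell placement and sensor noise each consume an independent substream of
    one seeded generator, so the truth does not depend on draw order.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_radii, rng_counts, rng_place, rng_noise = (np.random.default_rng(c) for c in ss.spawn(4))

    radii = _realized_radii(spec, rng_radii)
    if not spec.allow_contact:
        _check_contacts(spec, radii)

    grid = spec.grid
    h, w = grid.height_px, grid.width_px
    bg, fg = spec.brightness
    # thin rim slightly darker than the interior; kept well above the bg/fg
    # midpoint so a global threshold lands on the true disc edge
    rim = fg - 0.25 * (fg - bg)

    image = np.full((h, w), bg, dtype=float)
    # periodic electrode grid lines, one pixel wide, slightly darker than background
    image[:: grid.pitch_px, :] = bg * 0.8
    image[:, :: grid.pitch_px] = bg * 0.8

    label_mask = np.zeros((h, w), dtype=np.int32)
    gt_boxes: list[DetBox] = []
    for k, ((cx, cy), r) in enumerate(zip(spec.droplet_centers, radii), start=1):
        _paint_disc(image, cx, cy, r, rim)
        if r > 0.8:
            _paint_disc(image, cx, cy, r - 0.8, fg)
        _paint_disc(label_mask, cx, cy, r, k)  # pixel centers inside the full disc
        gt_boxes.append(DetBox(cx=cx, cy=cy, w=2 * r, h=2 * r, cls="droplet", confidence=1.0))
    # areas from the final mask so the label invariant holds even under allow_contact
    label_areas = np.bincount(label_mask.ravel(), minlength=len(radii) + 1)
    droplets = [
        DropletTruth(k, tuple(map(float, c)), float(r), int(label_areas[k]))
        for k, (c, r) in enumerate(zip(spec.droplet_centers, radii), start=1)
    ]

    # per-droplet cell counts ~ Poisson(lambda); uniform placement in the
    # margin-eroded disc (keeps whole cells strictly inside the droplet)
    cells: list[tuple[int | None, float, float]] = []
    counts = rng_counts.poisson(spec.cell_rate_lambda, size=len(droplets))
    for d, n_cells in zip(droplets, counts):
        margin = spec.cell_radius_px + 3.0  # keep cells clear of the blurred rim
        r_eff = max(d.radius - margin, 0.5)
        for _ in range(int(n_cells)):
            rho = r_eff * np.sqrt(rng_place.uniform())
            theta = rng_place.uniform(0, 2 * np.pi)
            x = d.center[0] + rho * np.cos(theta)
            y = d.center[1] + rho * np.sin(theta)
            cells.append((d.droplet_id, x, y))
            _paint_disc(image, x, y, spec.cell_radius_px, 0.15)
            gt_boxes.append(
                DetBox(
                    cx=x,
                    cy=y,
                    w=2 * spec.cell_radius_px,
                    h=2 * spec.cell_radius_px,
                    cls="cell",
                    confidence=1.0,
                )
            )

    if spec.blur_sigma_px > 0:
        image = ndi.gaussian_filter(image, spec.blur_sigma_px)
    if spec.noise_sigma > 0:
        image = image + rng_noise.normal(0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return SceneTruth(
        image=image,
        label_mask=label_mask,
        droplets=tuple(droplets),
        cells=tuple(cells),
        gt_boxes=tuple(gt_boxes),
    )
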