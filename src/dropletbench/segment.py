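"""Classical droplet segmentation and contour fitting.

The segmentation backend is a contract, not an architecture: any callable
``image -> label mask`` can stand behind the downstream analytics (a trained
network included).  This module ships a parameterised classical chain —
global threshold, morphological clean-up, hole filling, small-object
removal, optional distance-transform watershed for touching droplets — that
is sufficient on well-behaved droplet-array images, plus contour extraction
with least-squares ellipse fitting.

Area convention: the authoritative per-droplet area is the pixel count of
its label; the polygon (shoelace) area on half-integer boundary vertices is
reported alongside and may differ by the boundary discretisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

__all__ = ["SegmentationParams", "DropletContour", "segment_droplets", "extract_contours"]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the classical segmentation chain.

    ``threshold_method`` is ``"otsu"`` or a fixed float threshold.
    ``invert=True`` treats droplets as darker than the background.
    """

    threshold_method: str | float = "otsu"
    invert: bool = False
    open_radius_px: int = 1
    close_radius_px: int = 1
    fill_holes: bool = True
    min_area_px: int = 20
    split_touching: bool = False

    def __post_init__(self) -> None:
        if self.open_radius_px < 0 or self.close_radius_px < 0 or self.min_area_px < 0:
            raise ValueError("morphology radii and min_area_px must be >= 0")
        if isinstance(self.threshold_method, str) and self.threshold_method != "otsu":
            raise ValueError("threshold_method must be 'otsu' or a numeric threshold")


@dataclass
class DropletContour:
    """Closed contour of one segmented droplet.

    ``area_px`` is the authoritative pixel-count area; ``polygon_area`` the
    shoelace area of the traced boundary.  ``ellipse`` is
    ``(center, major_px, minor_px, angle_rad)`` from a least-squares fit to
    the boundary (axis lengths are full lengths, matching the second-moment
    convention), or ``None`` when the boundary is too short to fit.
    """

    droplet_id: int
    polygon: np.ndarray  # (N, 2) array of (x, y) vertices, closed
    area_px: float
    centroid: tuple[float, float]
    polygon_area: float
    ellipse: tuple[tuple[float, float], float, float, float] | None


def _relabel_raster(mask: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in raster order of each label's first pixel."""
    out = np.zeros_like(mask, dtype=np.int32)
    flat = mask.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return out
    order: dict[int, int] = {}
    for idx in nz:
        lab = flat[idx]
        if lab not in order:
            order[lab] = len(order) + 1
    lut = np.zeros(int(mask.max()) + 1, dtype=np.int32)
    for lab, new in order.items():
        lut[lab] = new
    out = lut[mask]
    return out


def segment_droplets(image: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Segment droplets in an intensity image into an integer label mask.

    Returns an int mask with 0 = background and labels 1..K numbered in
    raster order of each component's first pixel.  An image with no
    foreground yields an all-zero mask.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    if image.ndim != 2:
        raise ValueError("image must be 2-D (or RGB collapsed to 2-D)")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")

    work = -image if params.invert else image
    if params.threshold_method == "otsu":
        if np.ptp(work) == 0:
            return np.zeros(image.shape, dtype=np.int32)
        thresh = threshold_otsu(work)
    else:
        thresh = float(params.threshold_method)
        thresh = -thresh if params.invert else thresh
    binary = work > thresh

    if params.open_radius_px > 0:
        binary = ndi.binary_opening(binary, structure=morphology.disk(params.open_radius_px))
    if params.close_radius_px > 0:
        binary = ndi.binary_closing(binary, structure=morphology.disk(params.close_radius_px))
    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)

    if not binary.any():
        return np.zeros(image.shape, dtype=np.int32)

    labels, _ = ndi.label(binary)
    if params.split_touching:
        labels = _watershed_split(binary, labels)
    if params.min_area_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < params.min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
    return _relabel_raster(labels)


def _watershed_split(binary: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Separate touching discs by watershed on the distance transform.

    Seeds are local maxima of the distance transform separated by at least
    half the median equivalent radius of the current components.
    """
    distance = ndi.distance_transform_edt(binary)
    areas = np.bincount(labels.ravel())[1:]
    radii = np.sqrt(areas / np.pi)
    min_sep = max(int(np.median(radii) / 2), 1)
    coords = peak_local_max(distance, min_distance=min_sep, labels=labels, exclude_border=False)
    markers = np.zeros_like(labels)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return labels
    return segmentation.watershed(-distance, markers, mask=binary)


def extract_contours(mask: np.ndarray) -> list[DropletContour]:
    """Trace one closed contour per label and fit an ellipse to it.

    Vertices sit on half-integer boundary positions in (x, y) continuous
    coordinates.  Labels with fewer than 5 boundary points get
    ``ellipse=None``.
    """
    mask = np.asarray(mask)
    contours: list[DropletContour] = []
    for rp in measure.regionprops(mask.astype(np.int32)):
        lab = rp.label
        area_px = float(rp.area)
        # regionprops centroid is in index coordinates; pixel centers sit at +0.5
        cy, cx = rp.centroid
        centroid = (cx + 0.5, cy + 0.5)
        # trace within the padded bounding box only; offset back to image coords
        rsl, csl = rp.slice
        r_off, c_off = max(rsl.start - 1, 0), max(csl.start - 1, 0)
        window = mask[r_off : rsl.stop + 1, c_off : csl.stop + 1] == lab
        traced = measure.find_contours(window.astype(float), 0.5)
        if not traced:
            continue
        boundary = max(traced, key=len)  # (row, col) vertices
        polygon = np.column_stack([boundary[:, 1] + c_off + 0.5, boundary[:, 0] + r_off + 0.5])
        poly_area = _shoelace(polygon)
        ellipse = None
        if len(boundary) - 1 >= 5:  # distinct vertices (the trace closes on itself)
            params = _fit_ellipse(polygon)
            if params is not None:
                xc, yc, a, b, theta = params
                major, minor = (2 * a, 2 * b) if a >= b else (2 * b, 2 * a)
                if a < b:
                    theta = theta + np.pi / 2
                ellipse = ((float(xc), float(yc)), float(major), float(minor), float(theta % np.pi))
        contours.append(
            DropletContour(
                droplet_id=int(lab),
                polygon=polygon,
                area_px=area_px,
                centroid=centroid,
                polygon_area=poly_area,
                ellipse=ellipse,
            )
        )
    return contours


def _fit_ellipse(polygon: np.ndarray) -> tuple[float, ...] | None:
    """Least-squares conic fit of the boundary; returns (xc, yc, a, b, theta)."""
    pts = np.column_stack([polygon[:, 0], polygon[:, 1]])
    if hasattr(measure.EllipseModel, "from_estimate"):
        model = measure.EllipseModel.from_estimate(pts)
        if not model:
            return None
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
        return (float(xc), float(yc), float(a), float(b), float(theta))
    model = measure.EllipseModel()
    if not model.estimate(pts):
        return None
    return tuple(float(v) for v in model.params)


def _shoelace(polygon: np.ndarray) -> float:
    x, y = polygon[:, 0], polygon[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
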