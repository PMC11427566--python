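"""Shared I/O, dataset bookkeeping and configuration.

File formats: 16-bit grayscale PNG/TIFF for images and label masks, a JSON
annotation dialect with center-format boxes
(``{image, width, height, boxes: [{cx, cy, w, h, cls, conf}]}``, with a
flag for corner-format input), CSV reports via pandas, and YAML configs.
Round trips are lossless: boxes to 1e-6 px, masks bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml

from dropletbench.detect_eval import DetBox
from dropletbench.synth import GridSpec, SceneSpec

__all__ = [
    "DatasetSplit",
    "split_dataset",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_annotations",
    "write_annotations",
    "load_scene_config",
]


@dataclass(frozen=True)
class DatasetSplit:
    """A deterministic 60/20/20 train/validation/test index partition."""

    n_total: int
    train_ids: tuple[int, ...]
    val_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    seed: int


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def split_dataset(n: int, seed: int = 0) -> DatasetSplit:
    """Randomly split ``n`` samples 60/20/20 into train/validation/test.

    Validation and test each take ``round(0.2 n)`` (half-up), train the
    remainder — the rounding rule consistent with published
    3234 -> 1940/647/647, 5083 -> 3049/1017/1017 and 4046 -> 2428/809/809
    splits.  Deterministic for a fixed seed.
    """
    if n < 5:
        raise ValueError("need n >= 5 to form three non-empty sets")
    n_val = _round_half_up(0.2 * n)
    n_test = _round_half_up(0.2 * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val = perm[:n_val]
    test = perm[n_val : n_val + n_test]
    train = perm[n_val + n_test :]
    return DatasetSplit(
        n_total=n,
        train_ids=tuple(int(i) for i in np.sort(train)),
        val_ids=tuple(int(i) for i in np.sort(val)),
        test_ids=tuple(int(i) for i in np.sort(test)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# images and masks (16-bit grayscale)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    """Read an image back to float intensities in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    return arr.astype(float) / (info.max if info else 1.0)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    m = np.asarray(mask)
    if m.min() < 0 or m.max() > 65535:
        raise ValueError("label mask must fit in uint16")
    iio.imwrite(Path(path), m.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# annotation JSON


def write_annotations(
    path: str | Path, image_name: str, width: int, height: int, boxes: Sequence[DetBox]
) -> None:
    payload = {
        "image": image_name,
        "width": int(width),
        "height": int(height),
        "boxes": [
            {"cx": b.cx, "cy": b.cy, "w": b.w, "h": b.h, "cls": b.cls, "conf": b.confidence}
            for b in boxes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path: str | Path, corner_format: bool = False) -> tuple[dict, list[DetBox]]:
    """Read an annotation file; set ``corner_format`` for (x1,y1,x2,y2) boxes."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed annotation JSON ({exc})") from exc
    boxes = []
    for i, b in enumerate(payload.get("boxes", [])):
        try:
            if corner_format:
                box = DetBox.from_corners(
                    b["x1"], b["y1"], b["x2"], b["y2"], label=b.get("cls", "droplet"),
                    confidence=b.get("conf", 1.0),
                )
            else:
                box = DetBox(
                    cx=b["cx"], cy=b["cy"], w=b["w"], h=b["h"], cls=b.get("cls", "droplet"),
                    confidence=b.get("conf", 1.0),
                )
        except KeyError as exc:
            raise ValueError(f"{path}: box {i} missing field {exc}") from exc
        boxes.append(box)
    meta = {k: payload.get(k) for k in ("image", "width", "height")}
    return meta, boxes


# ---------------------------------------------------------------------------
# YAML configuration


def load_scene_config(path: str | Path, seed: int | None = None) -> SceneSpec:
    """Build a SceneSpec from a YAML config (grid + scene keys)."""
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        grid = GridSpec(**cfg["grid"])
        scene = dict(cfg["scene"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing config section {exc}") from exc
    scene["droplet_centers"] = tuple(tuple(c) for c in scene["droplet_centers"])
    if "brightness" in scene:
        scene["brightness"] = tuple(scene["brightness"])
    if seed is not None:
        scene["seed"] = seed
    return SceneSpec(grid=grid, **scene)
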