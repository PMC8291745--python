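"""Disk formats: images, transforms, displacement fields, reports, configs.

Transforms are stored as a row-major 3x3 homogeneous matrix in a plain-text
file plus a JSON sidecar (center, convention); displacement fields as
2-channel 32-bit TIFF (dx, dy in pixels) plus JSON metadata.  All writers
have exact-inverse readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .affine import AffineTransform2D
from .diffeo import DisplacementField
from .preprocess import PreprocessRecord

__all__ = [
    "read_image",
    "write_image",
    "save_affine",
    "load_affine",
    "save_field",
    "load_field",
    "save_json",
    "load_json",
]


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
        return
    if image.dtype != np.uint8:
        lo, hi = float(image.min()), float(image.max())
        scaled = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image, dtype=float)
        image = (255 * scaled).astype(np.uint8)
    iio.imwrite(path, image)


def save_affine(path, A: AffineTransform2D) -> None:
    path = Path(path)
    H = A.as_homogeneous()
    with open(path, "w") as fh:
        for row in H:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    meta = {
        "center": A.center.tolist(),
        "convention": "pull-back: output(x) = moving(linear @ (x - center) + center + translation); x = (column, row), 0-based pixel centers",
    }
    save_json(path.with_suffix(path.suffix + ".json"), meta)


def load_affine(path) -> AffineTransform2D:
    path = Path(path)
    H = np.loadtxt(path).reshape(3, 3)
    meta = load_json(path.with_suffix(path.suffix + ".json"))
    return AffineTransform2D.from_homogeneous(H, center=meta["center"])


def save_field(path, field: DisplacementField, meta: dict | None = None) -> None:
    path = Path(path)
    data = np.stack([field.u[..., 0], field.u[..., 1]]).astype(np.float32)
    tifffile.imwrite(path, data)
    info = {"channels": ["dx", "dy"], "units": "pixels",
            "convention": "phi(x) = x + u(x), pull-back"}
    info.update(meta or {})
    save_json(path.with_suffix(path.suffix + ".json"), info)


def load_field(path) -> DisplacementField:
    data = np.asarray(tifffile.imread(path), dtype=float)
    return DisplacementField(np.stack([data[0], data[1]], axis=-1))


def save_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, PreprocessRecord):
        return obj.to_json_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
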