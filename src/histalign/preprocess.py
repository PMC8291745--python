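"""Preprocessing of slide pairs into same-sized, padded working images.

Whole-slide inputs are far larger than the images deformable registration
can handle, so each slide is Gaussian-smoothed (anti-aliasing at the Nyquist
rate for the chosen stride), downsampled by a fixed factor ``f``, padded so
both images of a pair share a size with the tissue centered, padded again by
four similarity-kernel diameters to keep tissue away from the borders, and
the padding filled with Gaussian noise matched to the corner intensity
statistics.  Every geometric parameter is recorded so landmarks can be
mapped between full-resolution and working coordinates exactly.

Coordinate convention throughout: 0-based pixel centers, x = column,
y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessRecord",
    "smooth_and_resample",
    "pad_pair",
    "fill_padding_with_noise",
    "preprocess_pair",
]


@dataclass
class PreprocessRecord:
    """Geometry bookkeeping for one image of a preprocessed pair.

    A full-resolution point ``p`` maps to working coordinates as
    ``p * resample_factor + pad_offset`` (componentwise, (x, y) order).
    """

    resample_factor: float
    smoothing_sigma: float
    original_size: tuple[int, int]  # (W, H) full resolution
    resampled_size: tuple[int, int] = (0, 0)  # (W, H) after resampling
    pad_offset: tuple[int, int] = (0, 0)  # (dx, dy), working px
    working_size: tuple[int, int] = (0, 0)  # (W, H) after padding
    mask: np.ndarray | None = field(default=None, repr=False)
    corner_stats: tuple[float, float] | None = None  # (mean, std)
    noise_seed: int | None = None

    def to_working(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points * self.resample_factor + np.asarray(self.pad_offset, dtype=float)

    def to_original(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.pad_offset, dtype=float)) / self.resample_factor

    def to_json_dict(self) -> dict[str, Any]:
        d = {
            "resample_factor": self.resample_factor,
            "smoothing_sigma": self.smoothing_sigma,
            "original_size": list(self.original_size),
            "resampled_size": list(self.resampled_size),
            "pad_offset": list(self.pad_offset),
            "working_size": list(self.working_size),
            "corner_stats": list(self.corner_stats) if self.corner_stats else None,
            "noise_seed": self.noise_seed,
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict[str, Any]) -> "PreprocessRecord":
        rec = cls(
            resample_factor=d["resample_factor"],
            smoothing_sigma=d["smoothing_sigma"],
            original_size=tuple(d["original_size"]),
            resampled_size=tuple(d["resampled_size"]),
            pad_offset=tuple(d["pad_offset"]),
            working_size=tuple(d["working_size"]),
            corner_stats=tuple(d["corner_stats"]) if d.get("corner_stats") else None,
            noise_seed=d.get("noise_seed"),
        )
        if rec.working_size != (0, 0):
            W, H = rec.working_size
            w, h = rec.resampled_size
            dx, dy = rec.pad_offset
            mask = np.zeros((H, W), dtype=bool)
            mask[dy : dy + h, dx : dx + w] = True
            rec.mask = mask
        return rec


def smooth_and_resample(image: np.ndarray, f: float) -> tuple[np.ndarray, PreprocessRecord]:
    """Gaussian-smooth then downsample a single-channel image by factor ``f``.

    The smoothing sigma is half the downsampling stride, ``(1/f)/2`` original
    pixels, so that frequencies above the post-resampling Nyquist limit are
    suppressed before subsampling.  Resampling uses bilinear interpolation to
    the rounded target size; combined with the stride/2 smoothing this acts
    as an area-consistent (mass-preserving) downsampler.
    """
    if not 0 < f <= 1:
        raise ValueError(f"resample factor must be in (0, 1], got {f}")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {image.shape}")
    h, w = image.shape
    sigma = (1.0 / f) / 2.0
    out_h = max(1, int(round(h * f)))
    out_w = max(1, int(round(w * f)))
    if f == 1.0:
        out = image.copy()
        sigma = 0.0
    else:
        smoothed = ndimage.gaussian_filter(image, sigma=sigma, mode="nearest")
        # local-mean (area) averaging over one output-pixel footprint, then
        # sampling on the strided grid x = x_out / f, so that working
        # coordinates relate to full-resolution ones by exactly p_work = p * f
        footprint = max(1, int(round(1.0 / f)))
        smoothed = ndimage.uniform_filter(smoothed, size=footprint, mode="nearest")
        ys, xs = np.mgrid[0:out_h, 0:out_w].astype(float)
        out = ndimage.map_coordinates(
            smoothed, [ys / f, xs / f], order=1, mode="nearest"
        )
    record = PreprocessRecord(
        resample_factor=f,
        smoothing_sigma=sigma,
        original_size=(w, h),
        resampled_size=(out_w, out_h),
        working_size=(out_w, out_h),
    )
    mask = np.ones((out_h, out_w), dtype=bool)
    record.mask = mask
    return out, record


def pad_pair(
    a: np.ndarray,
    b: np.ndarray,
    kernel_radius: int,
    record_a: PreprocessRecord | None = None,
    record_b: PreprocessRecord | None = None,
) -> tuple[np.ndarray, np.ndarray, PreprocessRecord, PreprocessRecord]:
    """Pad two resampled images to one common, border-extended size.

    The shared size is the per-side maximum of the pair, then each side grows
    by ``2 * 4 * (2*kernel_radius + 1)`` (four similarity-kernel diameters on
    every edge) so tissue stays away from the boundary after the affine step.
    Each image is centered; pad offsets and binary masks of the original
    extent are stored on the records.  Padded pixels are zero until
    :func:`fill_padding_with_noise` runs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("pad_pair expects single-channel images")
    if kernel_radius < 1:
        raise ValueError(f"kernel_radius must be >= 1, got {kernel_radius}")
    diameter = 2 * kernel_radius + 1
    extra = 2 * 4 * diameter
    H = max(a.shape[0], b.shape[0]) + extra
    W = max(a.shape[1], b.shape[1]) + extra

    outs = []
    recs = []
    for img, rec in ((a, record_a), (b, record_b)):
        h, w = img.shape
        dy = (H - h) // 2
        dx = (W - w) // 2
        canvas = np.zeros((H, W), dtype=float)
        canvas[dy : dy + h, dx : dx + w] = img
        mask = np.zeros((H, W), dtype=bool)
        mask[dy : dy + h, dx : dx + w] = True
        if rec is None:
            rec = PreprocessRecord(
                resample_factor=1.0, smoothing_sigma=0.0, original_size=(w, h),
                resampled_size=(w, h),
            )
        rec.pad_offset = (dx, dy)
        rec.working_size = (W, H)
        rec.mask = mask
        outs.append(canvas)
        recs.append(rec)
    return outs[0], outs[1], recs[0], recs[1]


def fill_padding_with_noise(
    image: np.ndarray,
    record: PreprocessRecord,
    kernel_radius: int,
    seed: int,
) -> np.ndarray:
    """Fill the padded region with Gaussian noise matched to corner statistics.

    The four corner patches of the *unpadded* image, each one similarity-kernel
    diameter on a side, are pooled; padded pixels are drawn from
    Normal(mean, std) of that pool, clipped to the unpadded image's intensity
    range.  Deterministic for a given seed.  Zero-variance corners fill with
    the constant mean.
    """
    image = np.asarray(image, dtype=float)
    mask = record.mask
    if mask is None or mask.shape != image.shape:
        raise ValueError("record.mask missing or mismatched with image shape")
    dx, dy = record.pad_offset
    w, h = record.resampled_size
    inner = image[dy : dy + h, dx : dx + w]
    side = min(2 * kernel_radius + 1, h, w)
    corners = np.concatenate(
        [
            inner[:side, :side].ravel(),
            inner[:side, -side:].ravel(),
            inner[-side:, :side].ravel(),
            inner[-side:, -side:].ravel(),
        ]
    )
    mean = float(corners.mean())
    std = float(corners.std())
    record.corner_stats = (mean, std)
    record.noise_seed = int(seed)
    out = image.copy()
    pad_idx = ~mask
    n_pad = int(pad_idx.sum())
    if n_pad == 0:
        return out
    if std < 1e-15:
        out[pad_idx] = mean
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(mean, std, size=n_pad)
    lo, hi = float(inner.min()), float(inner.max())
    out[pad_idx] = np.clip(noise, lo, hi)
    return out


def preprocess_pair(
    a: np.ndarray,
    b: np.ndarray,
    f: float,
    kernel_scale: float = 40.0,
    seed: int = 0,
    noise_fill: bool = True,
) -> tuple[np.ndarray, np.ndarray, PreprocessRecord, PreprocessRecord, int]:
    """Full preprocessing chain for a registration-channel pair.

    Smooths and resamples both images, derives the similarity-kernel radius
    from the resampled fixed-image width, pads to a common size and fills the
    padding with corner-matched noise.  Returns the working images, their
    records, and the kernel radius used.
    """
    from .similarity import kernel_radius as _kr

    ra, rec_a = smooth_and_resample(a, f)
    rb, rec_b = smooth_and_resample(b, f)
    radius = _kr(ra.shape[1], kernel_scale)
    pa, pb, rec_a, rec_b = pad_pair(ra, rb, radius, rec_a, rec_b)
    if noise_fill:
        pa = fill_padding_with_noise(pa, rec_a, radius, seed=seed * 2 + 1)
        pb = fill_padding_with_noise(pb, rec_b, radius, seed=seed * 2 + 2)
    return pa, pb, rec_a, rec_b, radius
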