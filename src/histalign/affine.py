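"""Affine registration: brute-force rigid initialization + multi-resolution L-BFGS.

The affine stage minimizes the masked NCC dissimilarity over the six
coefficients of a 2D affine map.  Because NCC over rotations is highly
non-convex, the optimizer is seeded by a brute-force search over random
rigid transforms (angles ~ Normal(0, 180 deg), per-axis translations
~ Normal(0, 10% of image width)) evaluated at the coarsest pyramid level;
the best-scoring sample becomes the initial transform.  Refinement then runs
coarse-to-fine over a Gaussian pyramid, warm-starting each level.

Transforms use the pull-back (resampling) convention about the image
center: ``output(x) = moving(A @ (x - c) + c + t)``, with x = (column, row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .similarity import MetricConfig, dissimilarity

__all__ = [
    "AffineTransform2D",
    "InitSearchConfig",
    "resample_by_affine",
    "brute_force_rigid_init",
    "affine_register",
    "build_pyramid",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """2D affine map, fixed-space -> moving-space (pull-back convention).

    ``map_points`` sends a fixed-frame point x to ``linear @ (x - center)
    + center + translation`` in the moving frame.  Points are (x, y) =
    (column, row) pairs.
    """

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float).reshape(2, 2))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(2))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(2))
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls, center=(0.0, 0.0)) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), np.asarray(center, dtype=float))

    @classmethod
    def rigid(cls, angle_deg: float, translation, center=(0.0, 0.0)) -> "AffineTransform2D":
        a = np.deg2rad(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return cls(R, np.asarray(translation, dtype=float), np.asarray(center, dtype=float))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.center) @ self.linear.T + self.center + self.translation
        return out.reshape(np.shape(points))

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform2D(Ainv, -Ainv @ self.translation, self.center)

    def rescaled(self, s: float) -> "AffineTransform2D":
        """Same map expressed in coordinates scaled by ``1/s`` (x' = x/s)."""
        return AffineTransform2D(self.linear, self.translation / s, self.center / s)

    def as_homogeneous(self) -> np.ndarray:
        H = np.eye(3)
        H[:2, :2] = self.linear
        H[:2, 2] = self.translation + self.center - self.linear @ self.center
        return H

    @classmethod
    def from_homogeneous(cls, H: np.ndarray, center=(0.0, 0.0)) -> "AffineTransform2D":
        H = np.asarray(H, dtype=float)
        linear = H[:2, :2]
        c = np.asarray(center, dtype=float)
        t = H[:2, 2] - c + linear @ c
        return cls(linear, t, c)


@dataclass(frozen=True)
class InitSearchConfig:
    """Brute-force rigid search configuration."""

    n_samples: int = 4500
    rotation_stdev: float = 180.0  # degrees
    translation_stdev: float = 0.10  # fraction of image width
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.rotation_stdev <= 0 or self.translation_stdev <= 0:
            raise ValueError("stdevs must be positive")


def resample_by_affine(
    moving: np.ndarray, A: AffineTransform2D, out_size: tuple[int, int] | None = None
) -> np.ndarray:
    """Pull back ``moving`` through A: output(x) = moving(A(x)), bilinear.

    ``out_size`` is (W, H); defaults to the moving image size.  Out-of-bounds
    samples clamp to the nearest edge value.
    """
    moving = np.asarray(moving, dtype=float)
    if out_size is None:
        H, W = moving.shape
    else:
        W, H = out_size
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    mapped = A.map_points(pts)
    coords = np.stack([mapped[:, 1].reshape(H, W), mapped[:, 0].reshape(H, W)])
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest")


def build_pyramid(image: np.ndarray, factors=(4, 2, 1)) -> dict[int, np.ndarray]:
    """Gaussian pyramid by smoothing (sigma = stride/2) + strided subsampling.

    Level-k coordinates relate to the base by ``x = k * x_k`` exactly.
    """
    out = {}
    image = np.asarray(image, dtype=float)
    for k in factors:
        if k == 1:
            out[1] = image
        else:
            sm = ndimage.gaussian_filter(image, sigma=k / 2.0, mode="nearest")
            out[k] = sm[::k, ::k]
    return out


def _downsample_mask(mask: np.ndarray, k: int) -> np.ndarray:
    return mask[::k, ::k] if k > 1 else mask


def _level_radius(radius: int, k: int) -> int:
    # window radius shrinks with the level stride so windows cover the same
    # physical extent at every pyramid level
    return max(1, radius // k)


def brute_force_rigid_init(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: InitSearchConfig,
    metric: MetricConfig,
    mask: np.ndarray | None = None,
    radius: int | None = None,
    coarsest: int = 4,
    return_history: bool = False,
):
    """Random search over rigid transforms; returns the NCC-best as the init.

    Samples ``n_samples`` rigid transforms, evaluates the dissimilarity at
    the coarsest pyramid level, and returns the argmin (first occurrence on
    ties).  Deterministic for a given seed.  With ``return_history`` the
    per-sample dissimilarities are returned too (running-minimum envelope
    diagnostics).
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    H, W = fixed.shape
    center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    if radius is None:
        radius = metric.radius_for(W)
    k = coarsest
    fix_k = build_pyramid(fixed, (k,))[k]
    mov_k = build_pyramid(moving, (k,))[k]
    mask_k = _downsample_mask(mask, k) if mask is not None else None
    r_k = _level_radius(radius, k)
    cfg_k = MetricConfig(metric=metric.metric, kernel_scale=metric.kernel_scale, radius=r_k)

    rng = np.random.default_rng(config.seed)
    angles = rng.normal(0.0, config.rotation_stdev, size=config.n_samples)
    shifts = rng.normal(0.0, config.translation_stdev * W, size=(config.n_samples, 2))
    # evaluate identity alongside the samples so the result is never worse
    candidates = [AffineTransform2D.identity(center)]
    candidates += [
        AffineTransform2D.rigid(a, t, center) for a, t in zip(angles, shifts)
    ]
    scores = np.empty(len(candidates))
    for i, T in enumerate(candidates):
        warped = resample_by_affine(mov_k, T.rescaled(k))
        scores[i] = dissimilarity(fix_k, warped, cfg_k, mask_k)
    best = int(np.argmin(scores))
    result = candidates[best]
    if return_history:
        return result, scores[1:]
    return result


def affine_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    init: AffineTransform2D,
    metric: MetricConfig,
    pyramid=(4, 2, 1),
    mask: np.ndarray | None = None,
    radius: int | None = None,
    maxiter: int = 60,
) -> AffineTransform2D:
    """Multi-resolution affine refinement by L-BFGS-B.

    Minimizes the masked dissimilarity over the 6 raw affine coefficients,
    coarse-to-fine, warm-starting each level with the previous result
    (translations rescale with the level stride).  If the optimizer produces
    non-finite parameters the level falls back to its starting point; the
    returned transform never scores worse than ``init`` at full working
    resolution.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    H, W = fixed.shape
    if radius is None:
        radius = metric.radius_for(W)
    current = init
    for k in pyramid:
        fix_k = build_pyramid(fixed, (k,))[k]
        mov_k = build_pyramid(moving, (k,))[k]
        mask_k = _downsample_mask(mask, k) if mask is not None else None
        r_k = _level_radius(radius, k)
        cfg_k = MetricConfig(metric=metric.metric, kernel_scale=metric.kernel_scale, radius=r_k)
        T_k = current.rescaled(k)
        center_k = T_k.center
        # scale the linear coefficients so a unit parameter step moves an
        # edge pixel about one pixel, matching the translation units — the
        # raw 6-coefficient problem is otherwise badly conditioned
        s = max(fix_k.shape) / 2.0
        p0 = np.concatenate([T_k.linear.ravel() * s, T_k.translation])

        def objective(p):
            lin = p[:4].reshape(2, 2) / s
            if abs(np.linalg.det(lin)) < 1e-6:
                return 10.0
            T = AffineTransform2D(lin, p[4:6], center_k)
            warped = resample_by_affine(mov_k, T)
            return dissimilarity(fix_k, warped, cfg_k, mask_k)

        res = optimize.minimize(
            objective,
            p0,
            method="L-BFGS-B",
            jac="3-point",
            options={"maxiter": maxiter},
        )
        p = res.x
        if not np.all(np.isfinite(p)) or abs(np.linalg.det(p[:4].reshape(2, 2) / s)) < 1e-6:
            warnings.warn("affine optimizer diverged at level %d; keeping warm start" % k)
            p = p0
        elif objective(p) > objective(p0):
            p = p0
        T_k = AffineTransform2D(p[:4].reshape(2, 2) / s, p[4:6], center_k)
        current = AffineTransform2D(T_k.linear, T_k.translation * k, T_k.center * k)

    # descent contract at full resolution
    cfg = MetricConfig(metric=metric.metric, kernel_scale=metric.kernel_scale, radius=radius)
    d_init = dissimilarity(fixed, resample_by_affine(moving, init), cfg, mask)
    d_final = dissimilarity(fixed, resample_by_affine(moving, current), cfg, mask)
    if d_final > d_init:
        return init
    return current
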