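"""Greedy diffeomorphic refinement of the affine result.

Starting from the identity field, each iteration (i) computes the gradient
of the masked NCC dissimilarity with respect to the displacement, (ii)
smooths it with an isotropic Gaussian of scale ``sigma_s``, (iii) rescales
it so the largest update vector is ``step_cap`` pixels, forming a small
warp psi = Id + v, (iv) composes the running field with psi, and (v)
smooths the composed displacement with a Gaussian of scale ``sigma_t``.
For small enough steps and large enough sigma_s every psi has a positive
Jacobian determinant, and since diffeomorphisms are closed under
composition the accumulated field stays diffeomorphic.

The update runs coarse-to-fine over a 3-level pyramid; the field is
upsampled (displacements scaled by the stride ratio) between levels.
Larger ``sigma_s`` gives smoother updates; larger ``sigma_t`` gives less
total deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .affine import AffineTransform2D, build_pyramid, resample_by_affine, _downsample_mask, _level_radius
from .similarity import MetricConfig, dissimilarity, metric_value_and_gradient

__all__ = [
    "DisplacementField",
    "DiffeoParams",
    "identity_field",
    "warp_by_field",
    "compose_fields",
    "jacobian_determinant",
    "greedy_step",
    "diffeo_register",
]


@dataclass
class DisplacementField:
    """Per-pixel displacement u with phi(x) = x + u(x), pull-back convention.

    ``u`` has shape (H, W, 2) with components (ux, uy) in pixels; warping an
    image samples it at phi(x).  A field is accepted as diffeomorphic when
    the minimum Jacobian determinant of phi is positive.
    """

    u: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError(f"displacement field must have shape (H, W, 2), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[:2]

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(np.zeros(shape + (2,)))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Evaluate phi at arbitrary (x, y) points (bilinear, clamp-to-edge)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        coords = np.stack([pts[:, 1], pts[:, 0]])  # (row, col)
        ux = ndimage.map_coordinates(self.u[..., 0], coords, order=1, mode="nearest")
        uy = ndimage.map_coordinates(self.u[..., 1], coords, order=1, mode="nearest")
        out = pts + np.stack([ux, uy], axis=1)
        return out.reshape(np.shape(points))


def identity_field(shape: tuple[int, int]) -> DisplacementField:
    return DisplacementField.identity(shape)


def warp_by_field(image: np.ndarray, field_: DisplacementField) -> np.ndarray:
    """Pull back an image through phi: output(x) = image(x + u(x))."""
    image = np.asarray(image, dtype=float)
    H, W = field_.shape
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    coords = np.stack([ys + field_.u[..., 1], xs + field_.u[..., 0]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """(outer o inner)(x) = inner(x) + u_outer(inner(x)).

    u_outer is interpolated bilinearly at inner's arrival points
    (clamp-to-edge); composing with the identity returns the operand
    unchanged on grid points.
    """
    if outer.shape != inner.shape:
        raise ValueError("fields must share a grid")
    H, W = inner.shape
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    ax = xs + inner.u[..., 0]
    ay = ys + inner.u[..., 1]
    coords = np.stack([ay, ax])
    ox = ndimage.map_coordinates(outer.u[..., 0], coords, order=1, mode="nearest")
    oy = ndimage.map_coordinates(outer.u[..., 1], coords, order=1, mode="nearest")
    return DisplacementField(np.stack([inner.u[..., 0] + ox, inner.u[..., 1] + oy], axis=-1))


def jacobian_determinant(field_: DisplacementField) -> np.ndarray:
    """det of the Jacobian of phi(x) = x + u(x), central differences.

    Boundary rows/columns use one-sided differences (numpy.gradient).
    """
    u = field_.u
    if u.shape[0] < 2 or u.shape[1] < 2:
        raise ValueError("field must be at least 2x2")
    dux_dy, dux_dx = np.gradient(u[..., 0])
    duy_dy, duy_dx = np.gradient(u[..., 1])
    return (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx


@dataclass
class DiffeoParams:
    """Greedy diffeomorphic registration parameters.

    ``sigma_s`` smooths each update field, ``sigma_t`` the composed total
    field (both in pixels at the current pyramid level); ``iterations`` are
    per pyramid level, coarse to fine; ``step_cap`` bounds the largest
    per-iteration update vector (pixels).
    """

    sigma_s: float = 6.0
    sigma_t: float = 5.0
    iterations: tuple[int, ...] = (100, 50, 10)
    pyramid: tuple[int, ...] = (4, 2, 1)
    step_cap: float = 1.0
    #: percentile of the in-mask update magnitudes used as the step-size
    #: reference; a robust scale so a few high-contrast pixels do not starve
    #: the rest of the field (vectors above step_cap are clipped to it)
    step_percentile: float = 95.0

    def __post_init__(self):
        if self.sigma_s <= 0 or self.sigma_t <= 0:
            raise ValueError("sigma_s and sigma_t must be positive")
        if any(n < 0 for n in self.iterations):
            raise ValueError("iteration counts must be >= 0")
        if len(self.iterations) != len(self.pyramid):
            raise ValueError("one iteration count per pyramid level required")


def _smooth_field(u: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return u
    out = np.empty_like(u)
    for c in (0, 1):
        out[..., c] = ndimage.gaussian_filter(u[..., c], sigma=sigma, mode="nearest")
    return out


def greedy_step(
    fixed: np.ndarray,
    moving: np.ndarray,
    phi: DisplacementField,
    params: DiffeoParams,
    metric: MetricConfig,
    mask: np.ndarray | None = None,
    radius: int | None = None,
) -> DisplacementField:
    """One greedy update: smoothed-gradient step composed into the field.

    The negative metric gradient is smoothed with ``sigma_s``, scaled so the
    ``step_percentile``-th magnitude (within the mask) equals ``step_cap``,
    and any vector still longer than ``step_cap`` is clipped to it — so the
    largest update never exceeds ``step_cap`` pixels while typical tissue
    pixels keep a useful step size.  The scaled warp is composed into the
    running field and the result smoothed with ``sigma_t``.
    """
    warped = warp_by_field(moving, phi)
    _, grad = metric_value_and_gradient(fixed, warped, metric, mask, radius=radius)
    if not np.all(np.isfinite(grad)):
        warnings.warn("non-finite metric gradient; greedy step skipped")
        return phi
    v = _smooth_field(-grad, params.sigma_s)
    mag = np.sqrt((v**2).sum(axis=-1))
    sel = mag[mask] if mask is not None else mag
    sel = sel[sel > 0]
    if sel.size == 0:
        return phi
    ref = float(np.percentile(sel, params.step_percentile))
    if ref <= 0:
        return phi
    v = v * (params.step_cap / ref)
    mag = np.sqrt((v**2).sum(axis=-1))
    over = mag > params.step_cap
    if np.any(over):
        v[over] *= (params.step_cap / mag[over])[..., None]
    psi = DisplacementField(v)
    composed = compose_fields(phi, psi)
    return DisplacementField(_smooth_field(composed.u, params.sigma_t))


def diffeo_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    A: AffineTransform2D | None,
    params: DiffeoParams,
    metric: MetricConfig,
    mask: np.ndarray | None = None,
    radius: int | None = None,
) -> DisplacementField:
    """Greedy diffeomorphic registration after the affine stage.

    The moving image is first resampled through A (the field lives in the
    affine-resampled frame; the total mapping is A after phi).  Updates run
    per pyramid level, coarse-to-fine, the field upsampled and rescaled
    between levels.  If the final field scores worse than the post-affine
    starting point at full resolution, the identity field is returned
    instead; a non-positive final Jacobian raises a warning but still
    returns the field (with the diagnostic available via
    :func:`jacobian_determinant`).
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    H, W = fixed.shape
    if radius is None:
        radius = metric.radius_for(W)
    moving_a = resample_by_affine(moving, A) if A is not None else moving

    u = None
    prev_k = None
    for k, n_iter in zip(params.pyramid, params.iterations):
        fix_k = build_pyramid(fixed, (k,))[k]
        mov_k = build_pyramid(moving_a, (k,))[k]
        mask_k = _downsample_mask(mask, k) if mask is not None else None
        r_k = _level_radius(radius, k)
        cfg_k = MetricConfig(metric=metric.metric, kernel_scale=metric.kernel_scale, radius=r_k)
        shape_k = fix_k.shape
        if u is None:
            u = np.zeros(shape_k + (2,))
        else:
            u = _resize_field(u, shape_k, prev_k / k)
        # sigmas are stated in working-resolution pixels; hold them fixed in
        # physical scale, i.e. divide by the level stride at coarser levels
        params_k = DiffeoParams(
            sigma_s=params.sigma_s / k,
            sigma_t=params.sigma_t / k,
            iterations=params.iterations,
            pyramid=params.pyramid,
            step_cap=params.step_cap,
            step_percentile=params.step_percentile,
        )
        phi = DisplacementField(u)
        for _ in range(n_iter):
            phi = greedy_step(fix_k, mov_k, phi, params_k, cfg_k, mask_k, radius=r_k)
        u = phi.u
        prev_k = k

    if prev_k != 1:
        u = _resize_field(u, (H, W), prev_k)
    final = DisplacementField(u)

    cfg = MetricConfig(metric=metric.metric, kernel_scale=metric.kernel_scale, radius=radius)
    d0 = dissimilarity(fixed, moving_a, cfg, mask)
    d1 = dissimilarity(fixed, warp_by_field(moving_a, final), cfg, mask)
    if d1 > d0:
        warnings.warn("diffeomorphic stage did not improve the metric; returning identity field")
        return DisplacementField.identity((H, W))
    if float(jacobian_determinant(final).min()) <= 0:
        warnings.warn(
            "final field has a non-positive Jacobian determinant; "
            "consider a smaller step_cap or larger sigma_s"
        )
    return final


def _resize_field(u: np.ndarray, shape: tuple[int, int], ratio: float) -> np.ndarray:
    """Resample a level-p field onto a level-k grid (ratio = p/k).

    Level-k pixel x_k sits at level-p coordinate x_k / ratio (strided-pyramid
    convention x = k * x_k); displacement values rescale by the same ratio.
    """
    H, W = shape
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    coords = np.stack([ys / ratio, xs / ratio])
    out = np.empty((H, W, 2))
    for c in (0, 1):
        out[..., c] = ndimage.map_coordinates(u[..., c], coords, order=1, mode="nearest")
    return out * ratio
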