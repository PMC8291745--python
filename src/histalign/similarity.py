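"""Windowed similarity metrics: sum-table NCC and SSD, with gradients.

The normalized cross-correlation (NCC) of two images over a square window
centered at each pixel is the Pearson correlation of the two local patches;
it is insensitive to local affine intensity changes, which makes it the
metric of choice for differently stained sections.  Computing the five
window sums (I, J, I^2, J^2, I*J) with integral images (sum tables) makes
each NCC map O(N) regardless of window radius.

Windows are clipped at the image boundary, so every pixel owns a window
(the window-pixel count varies near the edges).  Windows whose variance in
either image is (near) zero get NCC = 0, a neutral value that avoids NaN
propagation.

The dissimilarity minimized by registration is the masked mean of
``1 - NCC`` (or the masked mean squared difference for SSD); its exact
gradient with respect to a per-pixel displacement of the moving image is
available for the greedy diffeomorphic update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricConfig",
    "kernel_radius",
    "window_sums",
    "ncc_map",
    "metric_value_and_gradient",
    "dissimilarity",
]

# windows whose intensity standard deviation is below this (in the units of
# the [0, 1]-normalized registration channels) are treated as featureless
# and contribute NCC = 0: flat background patches otherwise correlate at
# +/-1 through residual illumination gradients and swamp the tissue signal
MIN_WINDOW_STD = 1e-2


@dataclass(frozen=True)
class MetricConfig:
    """Similarity-metric configuration.

    ``kernel_scale`` divides the un-padded fixed-image width to give the NCC
    window radius; an explicit ``radius`` overrides that rule.
    """

    metric: str = "NCC"  # "NCC" or "SSD"
    kernel_scale: float = 40.0
    radius: int | None = None

    def __post_init__(self):
        if self.metric not in ("NCC", "SSD"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.kernel_scale < 1:
            raise ValueError("kernel_scale must be >= 1")
        if self.radius is not None and self.radius < 1:
            raise ValueError("radius must be >= 1")

    def radius_for(self, fixed_width: int) -> int:
        if self.radius is not None:
            return self.radius
        return kernel_radius(fixed_width, self.kernel_scale)


def kernel_radius(fixed_width: int, scale: float = 40.0) -> int:
    """Adaptive NCC kernel radius: floor(fixed_width / scale), at least 1."""
    return max(1, int(np.floor(fixed_width / scale)))


def window_sums(img: np.ndarray, r: int) -> np.ndarray:
    """Clipped box sums of ``img`` over (2r+1)-square windows via a sum table."""
    H, W = img.shape
    S = np.zeros((H + 1, W + 1), dtype=float)
    np.cumsum(img, axis=0, out=S[1:, 1:])
    np.cumsum(S[1:, 1:], axis=1, out=S[1:, 1:])
    y = np.arange(H)
    x = np.arange(W)
    y0 = np.clip(y - r, 0, H)
    y1 = np.clip(y + r + 1, 0, H)
    x0 = np.clip(x - r, 0, W)
    x1 = np.clip(x + r + 1, 0, W)
    return (
        S[np.ix_(y1, x1)] - S[np.ix_(y0, x1)] - S[np.ix_(y1, x0)] + S[np.ix_(y0, x0)]
    )


def _window_counts(shape: tuple[int, int], r: int) -> np.ndarray:
    H, W = shape
    y = np.arange(H)
    x = np.arange(W)
    ny = np.clip(y + r + 1, 0, H) - np.clip(y - r, 0, H)
    nx = np.clip(x + r + 1, 0, W) - np.clip(x - r, 0, W)
    return ny[:, None].astype(float) * nx[None, :]


def _window_stats(fixed: np.ndarray, moving: np.ndarray, r: int):
    n = _window_counts(fixed.shape, r)
    mI = window_sums(fixed, r) / n
    mJ = window_sums(moving, r) / n
    vI = window_sums(fixed * fixed, r) / n - mI * mI
    vJ = window_sums(moving * moving, r) / n - mJ * mJ
    cov = window_sums(fixed * moving, r) / n - mI * mJ
    return n, mI, mJ, np.maximum(vI, 0.0), np.maximum(vJ, 0.0), cov


def ncc_map(
    fixed: np.ndarray,
    moving: np.ndarray,
    radius: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel windowed NCC of two same-sized images, in [-1, 1].

    Equal (within 1e-6) to the naive per-window Pearson correlation with
    boundary-clipped windows.  Near-zero-variance windows and masked-out
    pixels return 0.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2:
        raise ValueError(f"images must be same-sized 2D arrays, got {fixed.shape} vs {moving.shape}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    _, _, _, vI, vJ, cov = _window_stats(fixed, moving, radius)
    valid = (vI > MIN_WINDOW_STD**2) & (vJ > MIN_WINDOW_STD**2)
    out = np.zeros_like(cov)
    denom = np.sqrt(vI * vJ, where=valid, out=np.ones_like(cov))
    np.divide(cov, denom, where=valid, out=out)
    np.clip(out, -1.0, 1.0, out=out)
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out


def dissimilarity(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: MetricConfig,
    mask: np.ndarray | None = None,
    radius: int | None = None,
) -> float:
    """Scalar dissimilarity: masked mean of 1 - NCC, or masked mean SSD."""
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if mask is None:
        mask = np.ones(fixed.shape, dtype=bool)
    m = mask.astype(float)
    M = m.sum()
    if M == 0:
        return 0.0
    if config.metric == "SSD":
        return float((m * (moving - fixed) ** 2).sum() / M)
    r = radius if radius is not None else config.radius_for(fixed.shape[1])
    nmap = ncc_map(fixed, moving, r)
    return float((m * (1.0 - nmap)).sum() / M)


def metric_value_and_gradient(
    fixed: np.ndarray,
    warped_moving: np.ndarray,
    config: MetricConfig,
    mask: np.ndarray | None = None,
    radius: int | None = None,
) -> tuple[float, np.ndarray]:
    """Dissimilarity and its gradient w.r.t. per-pixel displacement.

    The gradient field has shape (H, W, 2), components (d/dux, d/duy), and is
    the chain-rule product of the metric derivative with respect to the
    warped moving intensities and the spatial gradient of the warped moving
    image.  For NCC the intensity derivative is the exact adjoint of the
    window statistics, itself computed with box sums.
    """
    fixed = np.asarray(fixed, dtype=float)
    J = np.asarray(warped_moving, dtype=float)
    if fixed.shape != J.shape or fixed.ndim != 2:
        raise ValueError("images must be same-sized 2D arrays")
    if mask is None:
        mask = np.ones(fixed.shape, dtype=bool)
    m = mask.astype(float)
    M = m.sum()
    if M == 0:
        return 0.0, np.zeros(fixed.shape + (2,))

    if config.metric == "SSD":
        diff = J - fixed
        value = float((m * diff**2).sum() / M)
        dD_dJ = 2.0 * m * diff / M
    else:
        r = radius if radius is not None else config.radius_for(fixed.shape[1])
        n, mI, mJ, vI, vJ, cov = _window_stats(fixed, J, r)
        valid = (vI > MIN_WINDOW_STD**2) & (vJ > MIN_WINDOW_STD**2)
        sIsJ = np.sqrt(vI * vJ, where=valid, out=np.ones_like(cov))
        ncc = np.where(valid, cov / sIsJ, 0.0)
        np.clip(ncc, -1.0, 1.0, out=ncc)
        value = float((m * (1.0 - ncc)).sum() / M)
        # adjoint: dD/dJ(y) = -(1/M) * sum_{x in W_y} m_x * dNCC_x/dJ(y)
        w = m * valid
        alpha = np.where(valid, w / (n * sIsJ), 0.0)
        beta = np.where(valid, w * ncc / (n * np.maximum(vJ, MIN_WINDOW_STD**2)), 0.0)
        A = window_sums(alpha, r)
        B = window_sums(alpha * mI, r)
        C = window_sums(beta, r)
        E = window_sums(beta * mJ, r)
        dD_dJ = -(fixed * A - B - J * C + E) / M

    gy, gx = np.gradient(J)
    grad = np.stack([dD_dJ * gx, dD_dJ * gy], axis=-1)
    return value, grad
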