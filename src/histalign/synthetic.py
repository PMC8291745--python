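"""Synthetic histology-like fixtures with known ground-truth warps.

Generates textured "tissue" on a bright slide background, recolors it twice
through the stain forward model (two different stain recipes emulate
differently stained consecutive sections, including a DAB-brown recipe),
applies a known rigid/affine/smooth deformation to produce the moving
image, and emits exactly co-transformed landmark sets.  Everything is
deterministic given the configuration seed, so the whole registration
pipeline is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import pad_pair, fill_padding_with_noise
from .similarity import ncc_map
from .stains import FASTRED_FASTBLUE_DAB, StainSystem

__all__ = [
    "SynthConfig",
    "GroundTruthMap",
    "AffineMap",
    "SinusoidalMap",
    "GaussianBumpMap",
    "make_tissue_pair",
    "fig5_pad_demo",
]


# ---------------------------------------------------------------------------
# ground-truth maps (moving frame -> fixed frame, with exact/iterated inverse)


class GroundTruthMap:
    """A known warp G: moving-frame points -> fixed-frame points.

    The moving image is rendered as ``moving(y) = fixed_density(G(y))``, so
    a fixed-frame landmark p appears in the moving frame at ``G^-1(p)``
    (:meth:`to_moving`, solved by fixed-point iteration unless overridden).
    """

    def to_fixed(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """u with G(y) = y + u(y)."""
        return self.to_fixed(points) - np.asarray(points, dtype=float)

    def to_moving(self, points: np.ndarray, tol: float = 1e-12, maxiter: int = 200) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        y = pts.copy()
        for _ in range(maxiter):
            y_new = pts - self.displacement(y)
            if np.abs(y_new - y).max() < tol:
                y = y_new
                break
            y = y_new
        return y.reshape(np.shape(points))

    def warp_image(self, density: np.ndarray) -> np.ndarray:
        """Render the moving-frame image: moving(y) = density(G(y))."""
        H, W = density.shape
        ys, xs = np.mgrid[0:H, 0:W].astype(float)
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        g = np.atleast_2d(self.to_fixed(pts))
        coords = np.stack([g[:, 1].reshape(H, W), g[:, 0].reshape(H, W)])
        return ndimage.map_coordinates(density, coords, order=1, mode="nearest")

    def min_jacobian(self, shape: tuple[int, int]) -> float:
        """Minimum det(dG/dy) over the grid, by central differences."""
        H, W = shape
        ys, xs = np.mgrid[0:H, 0:W].astype(float)
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        u = self.displacement(pts)
        ux = u[:, 0].reshape(H, W)
        uy = u[:, 1].reshape(H, W)
        dux_dy, dux_dx = np.gradient(ux)
        duy_dy, duy_dx = np.gradient(uy)
        det = (1 + dux_dx) * (1 + duy_dy) - dux_dy * duy_dx
        return float(det.min())


@dataclass
class AffineMap(GroundTruthMap):
    """G(y) = L @ (y - c) + c + t (covers rigid as a special case)."""

    linear: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        self.center = np.asarray(self.center, dtype=float).reshape(2)

    @classmethod
    def rigid(cls, angle_deg: float, translation, center) -> "AffineMap":
        a = np.deg2rad(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return cls(R, translation, center)

    def to_fixed(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.center) @ self.linear.T + self.center + self.translation
        return out.reshape(np.shape(points))

    def to_moving(self, points: np.ndarray, **_) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        Linv = np.linalg.inv(self.linear)
        out = (pts - self.center - self.translation) @ Linv.T + self.center
        return out.reshape(np.shape(points))


@dataclass
class SinusoidalMap(GroundTruthMap):
    """u_x = a sin(2 pi y / wavelength + p0), u_y = a sin(2 pi x / wavelength + p1).

    Closed-form Jacobian: det = 1 - (2 pi a / wavelength)^2 cos(.) cos(.),
    strictly positive whenever a < wavelength / (2 pi).
    """

    amplitude: float
    wavelength: float
    phases: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.amplitude >= self.wavelength / (2 * np.pi):
            raise ValueError(
                f"amplitude {self.amplitude} too large for wavelength {self.wavelength}: "
                "ground-truth Jacobian would turn non-positive"
            )

    def to_fixed(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = 2 * np.pi / self.wavelength
        ux = self.amplitude * np.sin(k * pts[:, 1] + self.phases[0])
        uy = self.amplitude * np.sin(k * pts[:, 0] + self.phases[1])
        return (pts + np.stack([ux, uy], axis=1)).reshape(np.shape(points))


@dataclass
class ComposedMap(GroundTruthMap):
    """G = outer o inner; emulates a smooth deformation on top of the gross
    rigid mounting offset that consecutive sections always carry."""

    outer: GroundTruthMap
    inner: GroundTruthMap

    def to_fixed(self, points: np.ndarray) -> np.ndarray:
        return self.outer.to_fixed(self.inner.to_fixed(points))

    def to_moving(self, points: np.ndarray, **kw) -> np.ndarray:
        return self.inner.to_moving(self.outer.to_moving(points, **kw), **kw)


@dataclass
class GaussianBumpMap(GroundTruthMap):
    """Localized smooth push: u(y) = a * exp(-|y - c|^2 / (2 s^2)) * dir."""

    amplitude: float
    center: np.ndarray
    sigma: float
    direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        self.direction = self.direction / (n if n > 0 else 1.0)
        # max |grad u| = a/(s*sqrt(e)); keep it < 1 for invertibility
        if self.amplitude >= self.sigma * np.sqrt(np.e):
            raise ValueError("bump amplitude too large for its sigma: map would fold")

    def to_fixed(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts - self.center) ** 2).sum(axis=1)
        mag = self.amplitude * np.exp(-d2 / (2 * self.sigma**2))
        return (pts + mag[:, None] * self.direction).reshape(np.shape(points))


# ---------------------------------------------------------------------------
# tissue rendering


#: stain recipes: per-stain concentration weights applied to tissue density
STAIN_RECIPES = {
    "he_like": {"fastblue": 0.85, "fastred": 0.20},
    "dab_brown": {"dab": 0.70, "fastblue": 0.45},
    "fastred_heavy": {"fastred": 0.80, "fastblue": 0.25},
}


@dataclass
class SynthConfig:
    """Configuration of a synthetic slide pair.

    Sizes and warp parameters are in full-resolution pixels.  The defaults
    produce a 1250 px square slide that preprocesses (f = 1/5) to a ~250 px
    working image, with a sinusoidal warp of 8 working px amplitude and
    80 working px wavelength.
    """

    size: tuple[int, int] = (1250, 1250)  # (W, H)
    n_blobs: int = 14
    texture_scale: float = 30.0
    warp: str = "sinusoidal"  # rigid | affine | sinusoidal | gaussian-bump
    warp_amplitude: float = 40.0
    warp_wavelength: float = 400.0
    rotation_deg: float = 15.0
    scale: float = 1.0
    shear: float = 0.0
    translation: tuple[float, float] = (30.0, -20.0)
    n_landmarks: int = 24
    stain_pair: tuple[str, str] = ("he_like", "dab_brown")
    background_level: float = 0.95
    seed: int = 0


def _tissue_density(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    W, H = config.size
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    support = np.zeros((H, W))
    cx, cy = (W - 1) / 2, (H - 1) / 2
    span = min(W, H)
    for _ in range(config.n_blobs):
        bx = cx + rng.uniform(-0.22, 0.22) * span
        by = cy + rng.uniform(-0.22, 0.22) * span
        sx = rng.uniform(0.05, 0.14) * span
        sy = rng.uniform(0.05, 0.14) * span
        th = rng.uniform(0, np.pi)
        dx = (xs - bx) * np.cos(th) + (ys - by) * np.sin(th)
        dy = -(xs - bx) * np.sin(th) + (ys - by) * np.cos(th)
        support += np.exp(-0.5 * ((dx / sx) ** 2 + (dy / sy) ** 2))
    # sections have a crisp cut boundary, not a Gaussian fade: squash the
    # blob union through a steep sigmoid to get a sharp tissue edge
    support = 1.0 / (1.0 + np.exp(-(support - 0.45) * 18.0))
    texture = ndimage.gaussian_filter(rng.standard_normal((H, W)), config.texture_scale)
    texture = (texture - texture.min()) / (np.ptp(texture) + 1e-12)
    fine = ndimage.gaussian_filter(rng.standard_normal((H, W)), config.texture_scale / 4)
    fine = (fine - fine.min()) / (np.ptp(fine) + 1e-12)
    density = support * (0.35 + 0.45 * texture + 0.20 * fine)
    return np.clip(density, 0.0, 1.0), support


def _section_detail(shape, support, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Per-section fine structure: consecutive sections share coarse anatomy
    but contain different cells, so each rendering gets its own zero-mean
    fine-scale component.  The amplitude (0.03 of the density range) is
    calibrated so that perfectly aligned registration channels still
    correlate at NCC > 0.8, as they do on real adjacent sections."""
    fine = ndimage.gaussian_filter(rng.standard_normal(shape), scale / 5)
    fine = fine / (fine.std() + 1e-12)
    return 0.03 * support * fine


def _render_stain(
    density: np.ndarray,
    recipe_name: str,
    config: SynthConfig,
    rng: np.random.Generator,
    system: StainSystem = FASTRED_FASTBLUE_DAB,
) -> np.ndarray:
    """Color a density map through the OD forward model -> uint8-scale RGB."""
    recipe = STAIN_RECIPES[recipe_name]
    H, W = density.shape
    conc = np.zeros((H, W, 3))
    for stain, weight in recipe.items():
        conc[..., system.index_of(stain)] = weight * density
    od = conc @ system.od_matrix
    # slide background: slightly-below-white with mild illumination noise
    bg = config.background_level + 0.03 * ndimage.gaussian_filter(
        rng.standard_normal((H, W)), 50
    ) / 0.012
    bg = np.clip(bg, 0.92, 0.98)
    rgb = 255.0 * bg[..., None] * np.power(10.0, -od)
    return np.clip(rgb, 0.0, 255.0)


def _make_map(config: SynthConfig) -> GroundTruthMap:
    W, H = config.size
    center = np.array([(W - 1) / 2, (H - 1) / 2])
    if config.warp == "rigid":
        return AffineMap.rigid(config.rotation_deg, config.translation, center)
    if config.warp == "affine":
        a = np.deg2rad(config.rotation_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        S = np.array([[config.scale, config.shear], [0.0, config.scale]])
        return AffineMap(R @ S, config.translation, center)
    if config.warp == "sinusoidal":
        # consecutive sections are mounted independently, so the smooth
        # deformation rides on a gross rigid offset
        return ComposedMap(
            outer=SinusoidalMap(config.warp_amplitude, config.warp_wavelength, phases=(0.7, 2.1)),
            inner=AffineMap.rigid(config.rotation_deg, config.translation, center),
        )
    if config.warp == "gaussian-bump":
        return GaussianBumpMap(
            config.warp_amplitude, center, sigma=config.warp_wavelength / 2.0
        )
    raise ValueError(f"unknown warp type {config.warp!r}")


def make_tissue_pair(config: SynthConfig):
    """Generate a (fixed RGB, moving RGB, ground-truth map, landmarks) tuple.

    Landmark sets are exact under the ground-truth map; the generation
    raises if the requested warp would fold (non-positive Jacobian).
    Deterministic for a given config/seed.
    """
    from .landmarks import LandmarkSet

    rng = np.random.default_rng(config.seed)
    density, support = _tissue_density(config, rng)
    gt = _make_map(config)
    if gt.min_jacobian((config.size[1] // 4, config.size[0] // 4)) <= 0:
        raise ValueError("ground-truth warp folds (non-positive Jacobian)")
    rng_f = np.random.default_rng(config.seed + 1)
    rng_m = np.random.default_rng(config.seed + 2)
    dens_f = np.clip(density + _section_detail(density.shape, support, config.texture_scale, rng_f), 0, 1)
    dens_m = np.clip(density + _section_detail(density.shape, support, config.texture_scale, rng_m), 0, 1)
    moving_density = gt.warp_image(dens_m)

    fixed_rgb = _render_stain(dens_f, config.stain_pair[0], config, rng_f)
    moving_rgb = _render_stain(moving_density, config.stain_pair[1], config, rng_m)

    # landmarks mimic manual annotation: points on uniquely identifiable
    # structures, i.e. local maxima of the corner (min-eigenvalue) response
    # inside well-supported tissue, away from the image border
    from skimage.feature import corner_peaks, corner_shi_tomasi

    H, W = density.shape
    margin = int(0.15 * min(W, H))
    salience = corner_shi_tomasi(
        ndimage.gaussian_filter(density, config.texture_scale / 6), sigma=config.texture_scale / 3
    )
    eligible = (density > 0.35)
    eligible[:margin, :] = eligible[-margin:, :] = False
    eligible[:, :margin] = eligible[:, -margin:] = False
    salience = np.where(eligible, salience, 0.0)
    min_dist = int(config.texture_scale)
    while True:
        peaks = corner_peaks(
            salience, min_distance=min_dist, threshold_rel=0.02,
            num_peaks=4 * config.n_landmarks,
        )
        if len(peaks) >= config.n_landmarks or min_dist < 3:
            break
        min_dist //= 2  # relax spacing on small/sparse tissue
    if len(peaks) < config.n_landmarks:
        raise ValueError("not enough salient tissue structure for the requested landmark count")
    order = np.argsort(salience[peaks[:, 0], peaks[:, 1]])[::-1]
    peaks = peaks[order[: config.n_landmarks]]
    fixed_pts = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    moving_pts = gt.to_moving(fixed_pts)
    return (
        fixed_rgb,
        moving_rgb,
        gt,
        LandmarkSet(fixed_pts),
        LandmarkSet(moving_pts),
    )


# ---------------------------------------------------------------------------
# padding demonstration


def fig5_pad_demo(seed: int = 0, radius: int = 5) -> dict:
    """Contrast white padding vs corner-noise padding in the NCC response.

    Builds a gray-background textured image pair, pads both ways, and
    returns the NCC maps plus boundary/interior index masks.  White padding
    produces a strong spurious correlation along the pad border (both images
    share the same background-to-white edge); corner-matched noise does not.
    Windows that never touch the pad are identical between the fills.
    """
    rng = np.random.default_rng(seed)
    H = W = 160
    base = 0.55 + 0.02 * ndimage.gaussian_filter(rng.standard_normal((H, W)), 8) / 0.02
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    blob = np.exp(-(((xs - W / 2) / 28) ** 2 + ((ys - H / 2) / 22) ** 2))
    texture = ndimage.gaussian_filter(rng.standard_normal((H, W)), 3)
    texture /= np.abs(texture).max()
    img_a = np.clip(base - 0.35 * blob * (1 + 0.6 * texture), 0, 1)
    img_b = np.clip(np.roll(img_a, (2, 3), axis=(0, 1)) + 0.01 * rng.standard_normal((H, W)), 0, 1)

    pa, pb, rec_a, rec_b = pad_pair(img_a, img_b, radius)
    white_a = np.where(rec_a.mask, pa, 1.0)
    white_b = np.where(rec_b.mask, pb, 1.0)
    noise_a = fill_padding_with_noise(pa, rec_a, radius, seed=seed * 2 + 11)
    noise_b = fill_padding_with_noise(pb, rec_b, radius, seed=seed * 2 + 12)

    ncc_white = ncc_map(white_a, white_b, radius)
    ncc_noise = ncc_map(noise_a, noise_b, radius)

    mask = rec_a.mask
    # pad-side strip: windows centered in the padding whose support still
    # touches the original image border (where Fig-5-style square responses live)
    dilated = ndimage.binary_dilation(mask, iterations=radius + 1)
    boundary = dilated & ~mask
    interior = ndimage.binary_erosion(mask, iterations=radius + 2)
    return {
        "image": img_a,
        "white_a": white_a,
        "noise_a": noise_a,
        "ncc_white": ncc_white,
        "ncc_noise": ncc_noise,
        "boundary": boundary,
        "interior": interior,
        "mask": mask,
        "radius": radius,
    }
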