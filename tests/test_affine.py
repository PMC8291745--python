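"""Affine stage: transform algebra, resampling, brute-force init, L-BFGS."""

import numpy as np
import pytest
from scipy import ndimage

from histalign.affine import (
    AffineTransform2D,
    InitSearchConfig,
    affine_register,
    brute_force_rigid_init,
    resample_by_affine,
)
from histalign.similarity import MetricConfig, dissimilarity


def smooth_blob(shape=(96, 96), seed=0):
    """Rotationally asymmetric textured blob on a flat background, in [0, 1]."""
    rng = np.random.default_rng(seed)
    H, W = shape
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    img = np.exp(-(((xs - W * 0.55) / 18) ** 2 + ((ys - H * 0.45) / 10) ** 2))
    img += 0.7 * np.exp(-(((xs - W * 0.3) / 7) ** 2 + ((ys - H * 0.6) / 14) ** 2))
    img *= 1 + 0.15 * ndimage.gaussian_filter(rng.standard_normal(shape), 2)
    return (img - img.min()) / np.ptp(img)


class TestTransformAlgebra:
    def test_identity_maps_points_to_themselves(self):
        T = AffineTransform2D.identity(center=(10, 20))
        pts = np.array([[1.0, 2.0], [30.0, 40.0]])
        assert np.allclose(T.map_points(pts), pts)

    def test_inverse_round_trip(self):
        T = AffineTransform2D.rigid(33.0, (5.0, -2.0), center=(16.0, 16.0))
        pts = np.random.default_rng(0).random((10, 2)) * 30
        assert np.allclose(T.inverse().map_points(T.map_points(pts)), pts, atol=1e-12)

    def test_homogeneous_round_trip(self):
        T = AffineTransform2D(
            [[1.1, 0.05], [-0.02, 0.95]], [3.0, -4.0], center=(50.0, 40.0)
        )
        T2 = AffineTransform2D.from_homogeneous(T.as_homogeneous(), center=T.center)
        pts = np.random.default_rng(1).random((5, 2)) * 100
        assert np.allclose(T.map_points(pts), T2.map_points(pts), atol=1e-10)

    def test_rescaled_expresses_same_map(self):
        T = AffineTransform2D.rigid(20.0, (8.0, 6.0), center=(32.0, 32.0))
        Ts = T.rescaled(2.0)
        pts = np.array([[10.0, 14.0], [40.0, 22.0]])
        assert np.allclose(Ts.map_points(pts / 2.0) * 2.0, T.map_points(pts))

    def test_singular_linear_part_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform2D(np.zeros((2, 2)), np.zeros(2))


class TestResampleByAffine:
    def test_identity_returns_input(self):
        img = smooth_blob()
        out = resample_by_affine(img, AffineTransform2D.identity())
        assert np.allclose(out, img, atol=1e-12)

    def test_integer_translation_shifts_content_pullback(self):
        img = smooth_blob()
        T = AffineTransform2D(np.eye(2), [5.0, 3.0])
        out = resample_by_affine(img, T)
        # pull-back: output(x) = input(x + t) -> content moves by -t
        assert np.allclose(out[:-3, :-5], img[3:, 5:], atol=1e-12)

    def test_inverse_round_trip_high_psnr(self):
        img = ndimage.gaussian_filter(smooth_blob(), 2)
        T = AffineTransform2D.rigid(12.0, (4.0, -6.0), center=(48.0, 48.0))
        back = resample_by_affine(resample_by_affine(img, T), T.inverse())
        interior = (slice(12, -12), slice(12, -12))
        mse = float(np.mean((back[interior] - img[interior]) ** 2))
        psnr = 10 * np.log10(np.ptp(img) ** 2 / mse)
        assert psnr > 30


class TestBruteForceInit:
    def test_result_never_worse_than_identity_or_samples(self):
        img = smooth_blob()
        cfg = InitSearchConfig(n_samples=50, seed=3)
        metric = MetricConfig(radius=2)
        T, history = brute_force_rigid_init(
            img, img, cfg, metric, radius=2, return_history=True
        )
        d_best = dissimilarity(img, resample_by_affine(img, T), metric)
        d_id = dissimilarity(img, img, metric)
        assert d_best <= d_id + 1e-12
        assert len(history) == 50

    def test_recovers_thirty_degree_rotation(self):
        img = smooth_blob()
        H, W = img.shape
        center = ((W - 1) / 2, (H - 1) / 2)
        true = AffineTransform2D.rigid(30.0, (0.0, 0.0), center)
        moving = resample_by_affine(img, true.inverse())
        cfg = InitSearchConfig(n_samples=4500, seed=11)
        init = brute_force_rigid_init(img, moving, cfg, MetricConfig(radius=4), radius=4, coarsest=2)
        ang = np.rad2deg(np.arctan2(init.linear[1, 0], init.linear[0, 0]))
        assert ang == pytest.approx(30.0, abs=5.0)

    def test_running_minimum_is_monotone(self):
        img = smooth_blob(seed=5)
        moving = np.roll(img, (4, -3), axis=(0, 1))
        cfg = InitSearchConfig(n_samples=300, seed=7)
        _, history = brute_force_rigid_init(
            img, moving, cfg, MetricConfig(radius=3), radius=3, return_history=True
        )
        env = np.minimum.accumulate(history)
        assert np.all(np.diff(env) <= 0)

    def test_deterministic_given_seed(self):
        img = smooth_blob(seed=6)
        moving = np.roll(img, 3, axis=0)
        cfg = InitSearchConfig(n_samples=200, seed=13)
        metric = MetricConfig(radius=2)
        T1 = brute_force_rigid_init(img, moving, cfg, metric, radius=2)
        T2 = brute_force_rigid_init(img, moving, cfg, metric, radius=2)
        assert np.array_equal(T1.linear, T2.linear)
        assert np.array_equal(T1.translation, T2.translation)


class TestAffineRegister:
    def test_identity_pair_stays_identity(self):
        img = smooth_blob(seed=8)
        H, W = img.shape
        init = AffineTransform2D.identity(((W - 1) / 2, (H - 1) / 2))
        T = affine_register(img, img, init, MetricConfig(radius=3), radius=3)
        assert np.linalg.norm(T.linear - np.eye(2)) < 1e-3
        assert np.linalg.norm(T.translation) < 0.1

    def test_known_affine_recovered_below_half_pixel(self):
        img = ndimage.gaussian_filter(smooth_blob(shape=(128, 128), seed=9), 1)
        H, W = img.shape
        center = ((W - 1) / 2, (H - 1) / 2)
        a = np.deg2rad(10.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        S = np.array([[1.05, 0.02], [0.0, 1.05]])
        true = AffineTransform2D(R @ S, [6.0, -4.0], center)
        moving = resample_by_affine(img, true)  # moving content = img pulled by true
        init = AffineTransform2D.identity(center)
        est = affine_register(img, moving, init, MetricConfig(radius=4), radius=4)
        # perfect registration satisfies moving(est(x)) = fixed(x), i.e.
        # est equals the inverse of the generating map
        pts = np.mgrid[40:90:10, 40:90:10].reshape(2, -1).T.astype(float)
        err = np.hypot(*(est.map_points(pts) - true.inverse().map_points(pts)).T)
        assert err.mean() < 0.5

    def test_descent_contract(self):
        img = smooth_blob(seed=10)
        moving = np.roll(img, (2, 5), axis=(0, 1))
        H, W = img.shape
        init = AffineTransform2D.identity(((W - 1) / 2, (H - 1) / 2))
        metric = MetricConfig(radius=3)
        est = affine_register(img, moving, init, metric, radius=3)
        d_init = dissimilarity(img, resample_by_affine(moving, init), metric)
        d_est = dissimilarity(img, resample_by_affine(moving, est), metric)
        assert d_est <= d_init + 1e-12
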