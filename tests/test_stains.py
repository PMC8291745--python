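"""Color deconvolution: OD conversion, matrix inversion, channel selection."""

import numpy as np
import pytest

from histalign.stains import (
    FASTRED_FASTBLUE_DAB,
    StainSystem,
    deconvolve,
    invert_od_matrix,
    od_to_rgb,
    rgb_to_od,
    select_registration_channel,
)

# printed stain deconvolution matrix (rows FastRed, FastBlue, DAB)
EXPECTED_DECONV = np.array(
    [
        [-1.3283, 1.6219, 0.2597],
        [2.1280, -0.1584, -1.2561],
        [-1.1044, -0.4437, 2.1210],
    ]
)


class TestRgbToOd:
    def test_background_pixel_has_zero_od(self):
        img = np.full((2, 2, 3), 255.0)
        assert np.allclose(rgb_to_od(img, 255.0), 0.0)

    def test_tenth_of_background_gives_unit_od(self):
        img = np.full((1, 1, 3), 255.0)
        img[0, 0, 1] = 25.5
        od = rgb_to_od(img, 255.0)
        assert od[0, 0, 1] == pytest.approx(1.0)
        assert od[0, 0, 0] == pytest.approx(0.0)

    def test_round_trip_above_floor(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(2.0, 255.0, size=(8, 8, 3))
        od = rgb_to_od(img, 255.0)
        back = od_to_rgb(od, 255.0)
        assert np.allclose(back, img, atol=1e-9)

    def test_monotone_decreasing_in_intensity(self):
        img = np.stack([np.full((4, 4), v) for v in (50.0, 100.0)], axis=0)
        od = rgb_to_od(np.stack([img[0]] * 3, -1), 255.0)
        od2 = rgb_to_od(np.stack([img[1]] * 3, -1), 255.0)
        assert np.all(od > od2)

    def test_rejects_grayscale_and_bad_background(self):
        with pytest.raises(ValueError):
            rgb_to_od(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            rgb_to_od(np.zeros((4, 4, 3)), background=0.0)


class TestInvertOdMatrix:
    def test_identity(self):
        assert np.allclose(invert_od_matrix(np.eye(3)), np.eye(3))

    def test_printed_inverse_all_entries(self):
        inv = invert_od_matrix(FASTRED_FASTBLUE_DAB.od_matrix)
        assert np.allclose(inv, EXPECTED_DECONV, atol=5e-4)

    def test_product_is_identity_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = rng.uniform(0.2, 1.0, (3, 3)) + np.eye(3)
            inv = invert_od_matrix(m)
            assert np.allclose(m @ inv, np.eye(3), atol=1e-8)

    def test_singular_matrix_raises_with_determinant(self):
        m = np.ones((3, 3))
        with pytest.raises(ValueError, match="determinant"):
            invert_od_matrix(m)

    def test_double_inversion_is_involution(self):
        m = FASTRED_FASTBLUE_DAB.od_matrix
        assert np.allclose(invert_od_matrix(invert_od_matrix(m)), m, atol=1e-8)


class TestStainSystem:
    def test_rows_unit_normalized(self):
        norms = np.linalg.norm(FASTRED_FASTBLUE_DAB.od_matrix, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-3)

    def test_matrix_product_identity(self):
        s = FASTRED_FASTBLUE_DAB
        assert np.allclose(s.od_matrix @ s.deconv_matrix, np.eye(3), atol=1e-6)

    def test_rejects_unnormalized_rows(self):
        with pytest.raises(ValueError):
            StainSystem(("a", "b", "c"), np.eye(3) * 2.0)


class TestDeconvolve:
    def test_white_image_gives_zero_concentrations(self):
        img = np.full((4, 4, 3), 255.0)
        conc = deconvolve(img)
        assert np.allclose(conc, 0.0, atol=1e-9)

    def test_pure_stain_pixel_gives_unit_concentration(self):
        s = FASTRED_FASTBLUE_DAB
        for i in range(3):
            od = s.od_matrix[i]
            img = od_to_rgb(od.reshape(1, 1, 3), 255.0)
            conc = deconvolve(img, s)
            expected = np.zeros(3)
            expected[i] = 1.0
            assert np.allclose(conc[0, 0], expected, atol=1e-6)

    def test_known_mixture_recovered(self):
        s = FASTRED_FASTBLUE_DAB
        conc_true = np.array([0.0, 0.7, 0.3])  # 0.7 FastBlue + 0.3 DAB
        od = conc_true @ s.od_matrix
        img = od_to_rgb(od.reshape(1, 1, 3), 255.0)
        conc = deconvolve(img, s)
        assert np.allclose(conc[0, 0], conc_true, atol=1e-6)

    def test_od_recomposition(self):
        rng = np.random.default_rng(2)
        s = FASTRED_FASTBLUE_DAB
        conc_true = rng.uniform(0, 0.8, (5, 5, 3))
        od = conc_true @ s.od_matrix
        img = od_to_rgb(od, 255.0)
        conc = deconvolve(img, s)
        assert np.allclose(conc @ s.od_matrix, od, atol=1e-6)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(30, 250, (6, 7, 3))
        conc = deconvolve(img)
        rolled = deconvolve(np.roll(img, 2, axis=1))
        assert np.allclose(np.roll(conc, 2, axis=1), rolled)


class TestSelectRegistrationChannel:
    def test_dab_labels_use_fastblue_channel(self):
        # a FastBlue-stained gradient: the ESR path must track it
        s = FASTRED_FASTBLUE_DAB
        conc = np.zeros((4, 16, 3))
        conc[..., 1] = np.linspace(0, 0.9, 16)[None, :]
        img = od_to_rgb(conc @ s.od_matrix, 255.0)
        ch = select_registration_channel(img, "ESR")
        # pseudo-intensity: decreasing in concentration, range [0, 1]
        assert ch.min() >= 0.0 and ch.max() <= 1.0
        assert np.all(np.diff(ch[0]) < 0)

    def test_unknown_label_uses_luminance(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 255, (5, 5, 3))
        ch = select_registration_channel(img, "H&E")
        lum = (img / 255.0) @ np.array([0.299, 0.587, 0.114])
        lum = (lum - lum.min()) / np.ptp(lum)
        assert np.allclose(ch, lum)

    def test_constant_gray_gives_constant_channel(self):
        img = np.full((4, 4, 3), 128.0)
        for label in ("ESR", "H&E", ""):
            ch = select_registration_channel(img, label)
            assert ch.shape == (4, 4)
            assert np.ptp(ch) == pytest.approx(0.0)
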