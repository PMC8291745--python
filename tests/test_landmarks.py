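"""Landmark mapping and TRE / rTRE / robustness metrics with brute-force oracle."""

import numpy as np
import pytest

from histalign.affine import AffineTransform2D
from histalign.diffeo import DisplacementField
from histalign.landmarks import (
    LandmarkSet,
    aggregate_report,
    compute_robustness,
    compute_rtre,
    compute_tre,
    map_landmarks_to_original,
    map_landmarks_to_working,
    pair_report,
    read_landmarks_csv,
    warp_landmarks,
    write_landmarks_csv,
)
from histalign.preprocess import PreprocessRecord


def record(f=1 / 25, offset=(12, 8)):
    return PreprocessRecord(
        resample_factor=f, smoothing_sigma=0.0, original_size=(1000, 800),
        pad_offset=offset,
    )


class TestMapping:
    def test_working_mapping_example(self):
        lms = LandmarkSet([[100.0, 200.0]])
        out = map_landmarks_to_working(lms, record())
        assert np.allclose(out.points, [[16.0, 16.0]])

    def test_unit_factor_zero_offset_is_identity(self):
        lms = LandmarkSet([[5.0, 9.0], [1.0, 2.0]])
        out = map_landmarks_to_working(lms, record(f=1.0, offset=(0, 0)))
        assert np.allclose(out.points, lms.points)

    def test_round_trip(self):
        lms = LandmarkSet(np.random.default_rng(0).random((30, 2)) * 900)
        rec = record()
        back = map_landmarks_to_original(map_landmarks_to_working(lms, rec), rec)
        assert np.allclose(back.points, lms.points, atol=1e-9)


class TestWarpLandmarks:
    def test_identity_chain_leaves_points(self):
        lms = LandmarkSet([[3.0, 4.0], [10.0, 12.0]])
        out = warp_landmarks(lms, A=AffineTransform2D.identity(),
                             phi=DisplacementField.identity((20, 20)))
        assert np.allclose(out.points, lms.points)

    def test_translation_affine_shifts_all(self):
        lms = LandmarkSet([[3.0, 4.0], [10.0, 12.0]])
        A = AffineTransform2D(np.eye(2), [5.0, 0.0])
        out = warp_landmarks(lms, A=A)
        assert np.allclose(out.points - lms.points, [5.0, 0.0])

    def test_field_applied_before_affine(self):
        u = np.zeros((20, 20, 2))
        u[..., 1] = 2.0  # +2 in y everywhere
        phi = DisplacementField(u)
        A = AffineTransform2D(2 * np.eye(2), [0.0, 0.0])
        out = warp_landmarks(LandmarkSet([[4.0, 5.0]]), A=A, phi=phi)
        # phi first: (4,7); then linear doubling: (8,14)
        assert np.allclose(out.points, [[8.0, 14.0]])


class TestMetrics:
    def test_coincident_sets_zero(self):
        a = LandmarkSet([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(compute_tre(a, a), 0.0)

    def test_three_four_five(self):
        a = LandmarkSet([[0.0, 0.0]])
        b = LandmarkSet([[3.0, 4.0]])
        assert compute_tre(a, b)[0] == pytest.approx(5.0)

    def test_tre_rotation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.random((12, 2)) * 100
        b = rng.random((12, 2)) * 100
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        t1 = compute_tre(LandmarkSet(a), LandmarkSet(b))
        t2 = compute_tre(LandmarkSet(a @ R.T), LandmarkSet(b @ R.T))
        assert np.allclose(t1, t2, atol=1e-9)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_tre(LandmarkSet([[0, 0]]), LandmarkSet([[0, 0], [1, 1]]))

    def test_rtre_example(self):
        assert compute_rtre(np.array([5.0]), 300, 400)[0] == pytest.approx(0.01)
        assert compute_rtre(np.array([0.0]), 300, 400)[0] == 0.0

    def test_rtre_scale_invariance(self):
        tre = np.array([3.0, 7.0])
        assert np.allclose(compute_rtre(2 * tre, 600, 800), compute_rtre(tre, 300, 400))

    def test_robustness_examples(self):
        init = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert compute_robustness(init, init * 0.5) == 1.0
        assert compute_robustness(init, init.copy()) == 0.0  # ties not improved
        regist = np.array([0.5, 0.5, 0.5, 2.0, 2.0, 2.0])
        assert compute_robustness(init, regist) == 0.5


class TestOracleEquivalence:
    def test_metrics_match_brute_force_on_random_sets(self):
        """Eq-by-eq brute-force recomputation on 100 random landmark sets."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            L = int(rng.integers(2, 40))
            w, h = rng.uniform(100, 2000, 2)
            warped = rng.uniform(0, 1000, (L, 2))
            target = rng.uniform(0, 1000, (L, 2))
            initial = rng.uniform(0, 1000, (L, 2))
            tre = compute_tre(LandmarkSet(warped), LandmarkSet(target))
            rtre = compute_rtre(tre, w, h)
            tre_init = compute_tre(LandmarkSet(initial), LandmarkSet(target))
            rtre_init = compute_rtre(tre_init, w, h)
            rob = compute_robustness(rtre_init, rtre)
            # brute force re-computation
            diag = (w**2 + h**2) ** 0.5
            bf_tre = [
                ((warped[i, 0] - target[i, 0]) ** 2 + (warped[i, 1] - target[i, 1]) ** 2) ** 0.5
                for i in range(L)
            ]
            bf_rtre = [t / diag for t in bf_tre]
            bf_init = [
                (((initial[i, 0] - target[i, 0]) ** 2 + (initial[i, 1] - target[i, 1]) ** 2) ** 0.5) / diag
                for i in range(L)
            ]
            bf_rob = sum(r < ri for r, ri in zip(bf_rtre, bf_init)) / L
            assert np.allclose(tre, bf_tre, rtol=1e-12, atol=0)
            assert np.allclose(rtre, bf_rtre, rtol=1e-12, atol=0)
            assert rob == pytest.approx(bf_rob, abs=1e-12)


class TestAggregation:
    def _report(self, med, rob=1.0):
        tre = np.array([med, med])
        return pair_report(
            LandmarkSet([[0.0, 0.0], [med, 0.0]]),
            LandmarkSet([[med, 0.0], [2 * med, 0.0]]),
            LandmarkSet([[5 * med, 0.0], [6 * med, 0.0]]),
            (300.0, 400.0),
        )

    def test_single_pair_aggregates_equal_pair_stats(self):
        rep = self._report(3.0)
        agg = aggregate_report([rep])
        assert agg["average_median_rtre"] == rep.median_rtre
        assert agg["median_median_rtre"] == rep.median_rtre
        assert agg["average_robustness"] == rep.robustness

    def test_two_pair_average(self):
        import dataclasses
        from histalign.landmarks import MetricReport

        r1 = MetricReport(np.array([1.0]), np.array([0.002]), 1.0, 500.0)
        r2 = MetricReport(np.array([2.0]), np.array([0.004]), 1.0, 500.0)
        agg = aggregate_report([r1, r2])
        assert agg["average_median_rtre"] == pytest.approx(0.003)

    def test_permutation_invariance(self):
        from histalign.landmarks import MetricReport

        reps = [
            MetricReport(np.array([i + 1.0]), np.array([0.001 * (i + 1)]), 1.0, 500.0)
            for i in range(5)
        ]
        a1 = aggregate_report(reps)
        a2 = aggregate_report(reps[::-1])
        assert a1 == a2


class TestCsvRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        lms = LandmarkSet(np.random.default_rng(3).random((7, 2)) * 500)
        p = tmp_path / "lm.csv"
        write_landmarks_csv(p, lms)
        back = read_landmarks_csv(p)
        assert np.allclose(back.points, lms.points)

    def test_one_based_flag(self, tmp_path):
        p = tmp_path / "lm.csv"
        p.write_text("index,X,Y\n0,10,20\n")
        assert np.allclose(read_landmarks_csv(p, one_based=True).points, [[9.0, 19.0]])
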