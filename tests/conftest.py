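"""Shared fixtures: synthetic registration suites computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from histalign.diffeo import jacobian_determinant
from histalign.pipeline import (
    RunConfig,
    evaluate_result,
    register_pair,
    working_scale_errors,
)
from histalign.synthetic import SynthConfig, make_tissue_pair


@pytest.fixture(scope="session")
def rigid_scale_recovery_suite():
    """20 seeded rigid+scale warps registered with the affine stage only.

    Returns a list of dicts with per-pair median landmark errors at working
    resolution.
    """
    rng = np.random.default_rng(42)
    out = []
    for i in range(20):
        rot = float(rng.uniform(-30, 30))
        sc = float(rng.uniform(0.95, 1.05))
        tr = tuple(rng.uniform(-30, 30, 2))
        sh = float(rng.uniform(-0.02, 0.02))
        cfg = SynthConfig(
            size=(800, 800), warp="affine", rotation_deg=rot, scale=sc, shear=sh,
            translation=tr, seed=i, n_blobs=10,
            stain_pair=("he_like", "he_like"), n_landmarks=20,
        )
        fixed, moving, gt, flms, mlms = make_tissue_pair(cfg)
        rc = RunConfig(resample_factor=1 / 5, seed=200 + i, n_init=4500)
        res = register_pair(fixed, moving, rc, skip_diffeo=True)
        errs = working_scale_errors(res, flms, mlms)
        out.append(
            {
                "median_affine": float(np.median(errs["affine"])),
                "median_initial": float(np.median(errs["initial"])),
            }
        )
    return out


@pytest.fixture(scope="session")
def sinusoidal_recovery_suite():
    """Full two-step registration on the sinusoidal-warp fixtures (seeds 0-2).

    Each entry carries working-scale per-stage landmark errors, full-scale
    stage reports, and the final-field Jacobian diagnostic.
    """
    out = []
    for seed in (0, 1, 2):
        cfg = SynthConfig(seed=seed)
        fixed, moving, gt, flms, mlms = make_tissue_pair(cfg)
        rc = RunConfig(
            resample_factor=1 / 5, seed=100 + seed, n_init=4500,
            moving_stain_label="ERBB2",
        )
        res = register_pair(fixed, moving, rc)
        errs = working_scale_errors(res, flms, mlms)
        reports = evaluate_result(res, flms, mlms)
        out.append(
            {
                "seed": seed,
                "errors": errs,
                "reports": reports,
                "min_jacobian": float(jacobian_determinant(res.field).min()),
                "result": res,
                "landmarks": (flms, mlms),
            }
        )
    return out


@pytest.fixture(scope="session")
def small_pair():
    """A small, quick synthetic pair for pipeline/CLI plumbing tests."""
    cfg = SynthConfig(
        size=(600, 600), n_blobs=8, warp="rigid", rotation_deg=10.0,
        translation=(15.0, -10.0), n_landmarks=10,
        stain_pair=("he_like", "dab_brown"), seed=7,
    )
    fixed, moving, gt, flms, mlms = make_tissue_pair(cfg)
    return fixed, moving, gt, flms, mlms
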