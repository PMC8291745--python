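"""End-to-end registration pipeline: channel selection -> preprocessing ->
rigid brute force -> affine -> greedy diffeomorphic -> landmark evaluation.

This is the library core behind the command-line interface; each stage is a
thin call into the corresponding module, and every geometric parameter
needed to map landmarks between full-resolution and working space travels
in the :class:`RegistrationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .affine import AffineTransform2D, InitSearchConfig, affine_register, brute_force_rigid_init
from .diffeo import DiffeoParams, DisplacementField, diffeo_register, jacobian_determinant
from .landmarks import (
    LandmarkSet,
    MetricReport,
    aggregate_report,
    compute_rtre,
    compute_tre,
    map_landmarks_to_original,
    map_landmarks_to_working,
    pair_report,
    warp_landmarks,
)
from .preprocess import PreprocessRecord, preprocess_pair
from .similarity import MetricConfig
from .stains import select_registration_channel

__all__ = ["RunConfig", "RegistrationResult", "register_pair", "evaluate_result", "sweep"]


@dataclass
class RunConfig:
    """All pipeline defaults in one serializable record."""

    resample_factor: float = 1.0 / 25.0
    kernel_scale: float = 40.0
    sigma_s: float = 6.0
    sigma_t: float = 5.0
    iterations: tuple[int, ...] = (100, 50, 10)
    pyramid: tuple[int, ...] = (4, 2, 1)
    n_init: int = 4500
    rotation_stdev: float = 180.0
    translation_stdev: float = 0.10
    step_cap: float = 1.0
    metric: str = "NCC"
    seed: int = 0
    fixed_stain_label: str = ""
    moving_stain_label: str = ""

    def to_json_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["iterations"] = list(self.iterations)
        d["pyramid"] = list(self.pyramid)
        return d

    @classmethod
    def from_json_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "iterations" in d:
            d["iterations"] = tuple(d["iterations"])
        if "pyramid" in d:
            d["pyramid"] = tuple(d["pyramid"])
        return cls(**d)


@dataclass
class RegistrationResult:
    """Everything produced by one pair registration."""

    config: RunConfig
    fixed_work: np.ndarray
    moving_work: np.ndarray
    fixed_record: PreprocessRecord
    moving_record: PreprocessRecord
    kernel_radius: int
    init_transform: AffineTransform2D
    affine_transform: AffineTransform2D
    field: DisplacementField
    log: list = field(default_factory=list)

    def min_jacobian(self) -> float:
        return float(jacobian_determinant(self.field).min())


def _to_channel(image: np.ndarray, label: str) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        lo, hi = float(image.min()), float(image.max())
        return (image - lo) / (hi - lo) if hi > lo else image.astype(float)
    return select_registration_channel(image, label)


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: RunConfig | None = None,
    skip_diffeo: bool = False,
) -> RegistrationResult:
    """Run the full two-step registration of a slide pair.

    ``fixed``/``moving`` may be RGB (stain labels in the config pick the
    registration channel) or already-scalar images.
    """
    config = config or RunConfig()
    ch_f = _to_channel(fixed, config.fixed_stain_label)
    ch_m = _to_channel(moving, config.moving_stain_label)
    work_f, work_m, rec_f, rec_m, radius = preprocess_pair(
        ch_f, ch_m, config.resample_factor, config.kernel_scale, seed=config.seed
    )
    metric = MetricConfig(metric=config.metric, kernel_scale=config.kernel_scale, radius=radius)
    mask = rec_f.mask

    init_cfg = InitSearchConfig(
        n_samples=config.n_init,
        rotation_stdev=config.rotation_stdev,
        translation_stdev=config.translation_stdev,
        seed=config.seed,
    )
    init = brute_force_rigid_init(
        work_f, work_m, init_cfg, metric, mask=mask, radius=radius,
        coarsest=max(config.pyramid),
    )
    A = affine_register(
        work_f, work_m, init, metric, pyramid=config.pyramid, mask=mask, radius=radius
    )
    if skip_diffeo:
        phi = DisplacementField.identity(work_f.shape)
    else:
        params = DiffeoParams(
            sigma_s=config.sigma_s,
            sigma_t=config.sigma_t,
            iterations=config.iterations,
            pyramid=config.pyramid,
            step_cap=config.step_cap,
        )
        phi = diffeo_register(
            work_f, work_m, A, params, metric, mask=mask, radius=radius
        )
    return RegistrationResult(
        config=config,
        fixed_work=work_f,
        moving_work=work_m,
        fixed_record=rec_f,
        moving_record=rec_m,
        kernel_radius=radius,
        init_transform=init,
        affine_transform=A,
        field=phi,
    )


def _stage_report(
    result: RegistrationResult,
    fixed_lms: LandmarkSet,
    moving_lms: LandmarkSet,
    use_affine: bool,
    use_field: bool,
) -> MetricReport:
    wf = map_landmarks_to_working(fixed_lms, result.fixed_record)
    warped = warp_landmarks(
        wf,
        A=result.affine_transform if use_affine else None,
        phi=result.field if use_field else None,
    )
    warped_full = map_landmarks_to_original(warped, result.moving_record)
    w, h = result.moving_record.original_size
    return pair_report(warped_full, moving_lms, fixed_lms, (w, h))


def evaluate_result(
    result: RegistrationResult,
    fixed_lms: LandmarkSet,
    moving_lms: LandmarkSet,
) -> dict[str, Any]:
    """Landmark error report at each stage (initial / affine / affine+diffeo).

    Landmarks are full-resolution; the fixed image's set is mapped through
    the estimated pull-back chain into the moving frame and compared with
    the moving image's set.  rTRE normalizes by the moving (target) image's
    full-resolution diagonal.
    """
    w, h = result.moving_record.original_size
    tre_init = compute_tre(fixed_lms, moving_lms)
    rtre_init = compute_rtre(tre_init, w, h)
    initial = MetricReport(
        tre_init, rtre_init, robustness=0.0, diagonal=float(np.hypot(w, h))
    )
    affine_rep = _stage_report(result, fixed_lms, moving_lms, True, False)
    diffeo_rep = _stage_report(result, fixed_lms, moving_lms, True, True)
    return {
        "initial": initial,
        "affine": affine_rep,
        "affine_diffeo": diffeo_rep,
        "min_jacobian": result.min_jacobian(),
    }


def working_scale_errors(
    result: RegistrationResult,
    fixed_lms: LandmarkSet,
    moving_lms: LandmarkSet,
) -> dict[str, np.ndarray]:
    """Per-landmark errors in working-resolution pixels, per stage."""
    wf = map_landmarks_to_working(fixed_lms, result.fixed_record)
    wm = map_landmarks_to_working(moving_lms, result.moving_record)
    out = {}
    for name, (use_a, use_f) in {
        "initial": (False, False),
        "affine": (True, False),
        "affine_diffeo": (True, True),
    }.items():
        warped = warp_landmarks(
            wf,
            A=result.affine_transform if use_a else None,
            phi=result.field if use_f else None,
        )
        out[name] = compute_tre(warped, wm)
    return out


def sweep(
    pairs: list[tuple[np.ndarray, np.ndarray, LandmarkSet, LandmarkSet]],
    sigma_s_values,
    sigma_t_values,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Grid search over (sigma_s, sigma_t) on pairs with landmarks.

    The affine stage is shared across grid cells (it does not depend on the
    smoothing scales); each cell reruns only the diffeomorphic stage and
    scores the average-of-median rTRE.  Returns the grid as a long-format
    DataFrame and the argmin cell.
    """
    sigma_s_values = list(sigma_s_values)
    sigma_t_values = list(sigma_t_values)
    if not sigma_s_values or not sigma_t_values:
        raise ValueError("sigma ranges must be non-empty")
    if not pairs:
        raise ValueError("need at least one pair with landmarks")
    config = config or RunConfig()

    base = [register_pair(f, m, config, skip_diffeo=True) for f, m, _, _ in pairs]
    rows = []
    for ss in sigma_s_values:
        for st in sigma_t_values:
            params = DiffeoParams(
                sigma_s=ss, sigma_t=st, iterations=config.iterations,
                pyramid=config.pyramid, step_cap=config.step_cap,
            )
            reports = []
            for res, (_, _, flms, mlms) in zip(base, pairs):
                metric = MetricConfig(
                    metric=config.metric, kernel_scale=config.kernel_scale,
                    radius=res.kernel_radius,
                )
                phi = diffeo_register(
                    res.fixed_work, res.moving_work, res.affine_transform,
                    params, metric, mask=res.fixed_record.mask, radius=res.kernel_radius,
                )
                res2 = RegistrationResult(
                    config=config, fixed_work=res.fixed_work, moving_work=res.moving_work,
                    fixed_record=res.fixed_record, moving_record=res.moving_record,
                    kernel_radius=res.kernel_radius, init_transform=res.init_transform,
                    affine_transform=res.affine_transform, field=phi,
                )
                reports.append(_stage_report(res2, flms, mlms, True, True))
            agg = aggregate_report(reports)
            rows.append(
                {"sigma_s": ss, "sigma_t": st,
                 "average_median_rtre": agg["average_median_rtre"]}
            )
    df = pd.DataFrame(rows)
    best = df.loc[df["average_median_rtre"].idxmin()]
    return df, (float(best["sigma_s"]), float(best["sigma_t"]))
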