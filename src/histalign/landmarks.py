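"""Landmark mapping and registration-error metrics (TRE, rTRE, robustness).

Registration quality is judged by mapping manually placed landmarks from the
fixed image through the estimated transform chain into the moving image and
measuring the Euclidean distance to the corresponding manual landmarks
(target registration error, TRE).  TRE is normalized by the target-image
diagonal to make it comparable across image sizes (rTRE), and robustness is
the fraction of a pair's landmarks whose rTRE strictly decreased relative
to no registration.

Landmark CSV dialect: header row, columns (index, X, Y); X is the column
coordinate, 0-based, full-resolution pixels (flip ``one_based`` when the
source files count from 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affine import AffineTransform2D
from .diffeo import DisplacementField
from .preprocess import PreprocessRecord

__all__ = [
    "LandmarkSet",
    "MetricReport",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "map_landmarks_to_working",
    "map_landmarks_to_original",
    "warp_landmarks",
    "compute_tre",
    "compute_rtre",
    "compute_robustness",
    "pair_report",
    "aggregate_report",
]


@dataclass
class LandmarkSet:
    """Ordered 2D landmark coordinates (x, y), full-resolution pixels."""

    points: np.ndarray
    ids: list | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[-1] != 2:
            raise ValueError(f"landmarks must be (L, 2), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.ids is None:
            self.ids = list(range(len(self.points)))

    def __len__(self) -> int:
        return len(self.points)


def read_landmarks_csv(path, one_based: bool = False) -> LandmarkSet:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    pts = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    if one_based:
        pts = pts - 1.0
    ids = df[df.columns[0]].tolist() if df.shape[1] > 2 else None
    return LandmarkSet(pts, ids)


def write_landmarks_csv(path, lms: LandmarkSet) -> None:
    df = pd.DataFrame({"index": lms.ids, "X": lms.points[:, 0], "Y": lms.points[:, 1]})
    df.to_csv(path, index=False)


def map_landmarks_to_working(lms: LandmarkSet, record: PreprocessRecord) -> LandmarkSet:
    """Full-resolution -> working coordinates: p' = p*f + pad_offset."""
    return LandmarkSet(record.to_working(lms.points), list(lms.ids))


def map_landmarks_to_original(lms: LandmarkSet, record: PreprocessRecord) -> LandmarkSet:
    """Working -> full-resolution coordinates (inverse affine bookkeeping)."""
    return LandmarkSet(record.to_original(lms.points), list(lms.ids))


def warp_landmarks(
    lms: LandmarkSet,
    A: AffineTransform2D | None = None,
    phi: DisplacementField | None = None,
) -> LandmarkSet:
    """Map working-space fixed-image landmarks into the moving frame.

    Applies the same pull-back map used to resample the moving image,
    evaluated pointwise: first the displacement field phi (bilinear,
    clamp-to-edge), then the affine A.
    """
    pts = lms.points
    if phi is not None:
        pts = phi.map_points(pts)
    if A is not None:
        pts = A.map_points(pts)
    return LandmarkSet(pts, list(lms.ids))


def compute_tre(warped: LandmarkSet, target: LandmarkSet) -> np.ndarray:
    """Per-landmark Euclidean distance between warped and target landmarks."""
    if len(warped) != len(target):
        raise ValueError(f"landmark count mismatch: {len(warped)} vs {len(target)}")
    d = warped.points - target.points
    return np.sqrt((d**2).sum(axis=1))


def compute_rtre(tre: np.ndarray, w: float, h: float) -> np.ndarray:
    """TRE normalized by the target-image diagonal sqrt(w^2 + h^2)."""
    if w <= 0 or h <= 0:
        raise ValueError("image dimensions must be positive")
    return np.asarray(tre, dtype=float) / float(np.hypot(w, h))


def compute_robustness(rtre_init: np.ndarray, rtre_regist: np.ndarray) -> float:
    """Fraction of landmarks whose rTRE strictly decreased (ties don't count)."""
    rtre_init = np.asarray(rtre_init, dtype=float)
    rtre_regist = np.asarray(rtre_regist, dtype=float)
    if rtre_init.shape != rtre_regist.shape:
        raise ValueError("rTRE arrays must have equal length")
    return float(np.mean(rtre_regist < rtre_init))


@dataclass
class MetricReport:
    """Per-pair landmark error report."""

    tre: np.ndarray
    rtre: np.ndarray
    robustness: float
    diagonal: float
    median_rtre: float = field(init=False)
    average_rtre: float = field(init=False)
    max_rtre: float = field(init=False)

    def __post_init__(self):
        self.tre = np.asarray(self.tre, dtype=float)
        self.rtre = np.asarray(self.rtre, dtype=float)
        self.median_rtre = float(np.median(self.rtre))
        self.average_rtre = float(np.mean(self.rtre))
        self.max_rtre = float(np.max(self.rtre))

    def to_json_dict(self) -> dict:
        return {
            "median_rtre": self.median_rtre,
            "average_rtre": self.average_rtre,
            "max_rtre": self.max_rtre,
            "robustness": self.robustness,
            "diagonal": self.diagonal,
            "tre": self.tre.tolist(),
            "rtre": self.rtre.tolist(),
        }


def pair_report(
    warped: LandmarkSet,
    target: LandmarkSet,
    initial: LandmarkSet,
    target_size: tuple[float, float],
) -> MetricReport:
    """Build a MetricReport for one pair.

    ``target_size`` is (w, h) of the target image at full resolution;
    ``initial`` holds the fixed landmarks before any registration (for the
    robustness baseline).
    """
    w, h = target_size
    tre = compute_tre(warped, target)
    rtre = compute_rtre(tre, w, h)
    rtre_init = compute_rtre(compute_tre(initial, target), w, h)
    return MetricReport(tre, rtre, compute_robustness(rtre_init, rtre), float(np.hypot(w, h)))


def aggregate_report(reports: list[MetricReport]) -> dict:
    """Challenge-style aggregates over pairs (averages/medians of per-pair stats)."""
    if not reports:
        raise ValueError("need at least one pair report")
    med = np.array([r.median_rtre for r in reports])
    avg = np.array([r.average_rtre for r in reports])
    rob = np.array([r.robustness for r in reports])
    return {
        "average_median_rtre": float(med.mean()),
        "median_median_rtre": float(np.median(med)),
        "average_average_rtre": float(avg.mean()),
        "median_average_rtre": float(np.median(avg)),
        "average_robustness": float(rob.mean()),
        "median_robustness": float(np.median(rob)),
        "n_pairs": len(reports),
    }
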