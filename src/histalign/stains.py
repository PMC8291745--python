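"""Stain color deconvolution (Ruifrok–Johnston linear unmixing).

Immunohistochemical slides that contain diaminobenzidine (DAB) have a
brown-dominating appearance with heavy background staining.  Separating the
image into per-stain optical-density contributions and registering on the
FastBlue channel removes that artefact while preserving tissue structure.

The mixing model is linear in optical density (OD): each stain contributes an
RGB OD triplet (unit-normalized), and the observed OD at a pixel is the
concentration-weighted sum of the stain triplets.  Inverting the 3x3 stain
matrix therefore recovers per-stain concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainSystem",
    "FASTRED_FASTBLUE_DAB",
    "rgb_to_od",
    "od_to_rgb",
    "invert_od_matrix",
    "deconvolve",
    "select_registration_channel",
]

#: Intensity floor (on a 0-255 scale) applied before the log to avoid -inf.
OD_INTENSITY_FLOOR = 1.0

#: Slide labels whose stain includes DAB and therefore go through deconvolution.
DAB_STAIN_LABELS = frozenset({"ESR", "ERBB2"})

#: Rec. 601 luma weights used for non-DAB slides.
_LUMA = np.array([0.299, 0.587, 0.114])


def invert_od_matrix(od_matrix: np.ndarray) -> np.ndarray:
    """Invert a 3x3 stain OD matrix, giving the color deconvolution matrix.

    Raises
    ------
    ValueError
        If the matrix is singular (determinant reported in the message).
    """
    od_matrix = np.asarray(od_matrix, dtype=float)
    if od_matrix.shape != (3, 3):
        raise ValueError(f"expected a 3x3 OD matrix, got shape {od_matrix.shape}")
    det = np.linalg.det(od_matrix)
    if not np.isfinite(det) or abs(det) < 1e-12:
        raise ValueError(f"OD matrix is singular (determinant {det:g}); cannot deconvolve")
    return np.linalg.inv(od_matrix)


@dataclass(frozen=True)
class StainSystem:
    """A named triplet of stains with its OD mixing matrix and inverse.

    ``od_matrix`` rows are stains, columns are (R, G, B) OD components; each
    row is unit-normalized.  ``deconv_matrix`` is its inverse, recomputed at
    full precision on construction.
    """

    stain_names: tuple[str, str, str]
    od_matrix: np.ndarray
    deconv_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        od = np.asarray(self.od_matrix, dtype=float)
        if od.shape != (3, 3):
            raise ValueError(f"od_matrix must be 3x3, got {od.shape}")
        norms = np.linalg.norm(od, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError(f"od_matrix rows must be unit-normalized; norms {norms}")
        object.__setattr__(self, "od_matrix", od)
        object.__setattr__(self, "deconv_matrix", invert_od_matrix(od))

    @classmethod
    def from_unnormalized(cls, stain_names, rows) -> "StainSystem":
        rows = np.asarray(rows, dtype=float)
        rows = rows / np.linalg.norm(rows, axis=1, keepdims=True)
        return cls(tuple(stain_names), rows)

    def index_of(self, stain: str) -> int:
        names = [s.lower() for s in self.stain_names]
        return names.index(stain.lower())


#: Default stain system: FastRed / FastBlue / DAB unit OD triplets.
FASTRED_FASTBLUE_DAB = StainSystem(
    stain_names=("fastred", "fastblue", "dab"),
    od_matrix=np.array(
        [
            [0.2140, 0.8517, 0.4782],  # FastRed
            [0.7489, 0.6062, 0.2673],  # FastBlue
            [0.2681, 0.5703, 0.7764],  # DAB
        ]
    ),
)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {image.shape}")
    return image


def rgb_to_od(image: np.ndarray, background: float | np.ndarray = 255.0) -> np.ndarray:
    """Convert RGB intensities to optical density per channel.

    OD_c = -log10(max(I_c, floor) / background_c).  Intensities at the
    background level map to OD 0; darker pixels map to larger OD.
    """
    image = _check_rgb(image).astype(float)
    background = np.broadcast_to(np.asarray(background, dtype=float), (3,))
    if np.any(background <= 0):
        raise ValueError(f"background intensities must be positive, got {background}")
    floor = OD_INTENSITY_FLOOR * background / 255.0
    clipped = np.maximum(image, floor)
    return -np.log10(clipped / background)


def od_to_rgb(od: np.ndarray, background: float | np.ndarray = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (no floor applied)."""
    od = np.asarray(od, dtype=float)
    background = np.broadcast_to(np.asarray(background, dtype=float), (3,))
    return background * np.power(10.0, -od)


def deconvolve(
    image: np.ndarray,
    system: StainSystem = FASTRED_FASTBLUE_DAB,
    background: float | np.ndarray = 255.0,
) -> np.ndarray:
    """Unmix an RGB image into per-stain concentration channels.

    Returns an (H, W, 3) array whose channel order follows
    ``system.stain_names``.  Concentrations reproduce the pixel OD through
    ``od = od_matrix.T @ concentrations``.
    """
    od = rgb_to_od(image, background)
    # od_row = conc_row @ od_matrix, so conc_row = od_row @ od_matrix^-1
    return od @ system.deconv_matrix


def _rescale_unit(channel: np.ndarray) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    if hi - lo < 1e-12:
        return np.clip(channel, 0.0, 1.0)
    return (channel - lo) / (hi - lo)


def select_registration_channel(
    image: np.ndarray,
    stain_label: str = "",
    system: StainSystem = FASTRED_FASTBLUE_DAB,
    background: float | np.ndarray = 255.0,
) -> np.ndarray:
    """Pick the scalar channel used for registration, rescaled to [0, 1].

    DAB-containing slides (ESR, ERBB2 labels) use the FastBlue channel of the
    deconvolution, re-rendered as a single-stain pseudo-intensity
    (10^-concentration) so its polarity — dark tissue on a bright
    background — matches the luminance images used for every other label.
    Non-DAB labels fall through to Rec. 601 luminance of the RGB input.
    """
    image = _check_rgb(image)
    if stain_label.upper() in DAB_STAIN_LABELS:
        conc = deconvolve(image, system, background)
        channel = np.power(10.0, -conc[..., system.index_of("fastblue")])
    else:
        bg = np.broadcast_to(np.asarray(background, dtype=float), (3,))
        channel = (image.astype(float) / bg) @ _LUMA
    return _rescale_unit(channel)
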