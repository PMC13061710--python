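"""Macenko stain separation and standardization for H&E tiles.

Pixels live in [0, 1] (background intensity 1.0 by default; 8-bit
images are rescaled on load).  Optical density is od = -log10(I / I0),
so stains combine additively (Beer-Lambert).  The stain matrix has two
unit-norm columns (hematoxylin, eosin) found from the extreme angles of
the thresholded OD point cloud in its principal plane; concentrations
are non-negative least squares against that basis, scaled to a target
profile and re-rendered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateStainError",
    "StainProfile",
    "DEFAULT_STAIN_MATRIX",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "estimate_concentrations",
    "estimate_stain_profile",
    "normalize_stains",
    "default_target_profile",
]

log = logging.getLogger(__name__)

# Canonical H&E stain vectors (OD space, unit columns): hematoxylin, eosin.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.65, 0.07],
     [0.70, 0.99],
     [0.29, 0.11]]
)
DEFAULT_STAIN_MATRIX = DEFAULT_STAIN_MATRIX / np.linalg.norm(
    DEFAULT_STAIN_MATRIX, axis=0, keepdims=True
)

DEFAULT_OD_THRESHOLD = 0.15
DEFAULT_ANGLE_PERCENTILE = 1.0
DEFAULT_REGULARIZATION = 0.01
CONCENTRATION_PERCENTILE = 99.0


class DegenerateStainError(ValueError):
    """Raised when a tile does not contain enough stained tissue for
    stain-vector estimation (e.g. blank or single-color tiles)."""


def _validate_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 2):
        raise ValueError("stain matrix must be 3x2")
    norms = np.linalg.norm(m, axis=0)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("stain matrix columns must be unit norm")
    if np.linalg.matrix_rank(m) < 2:
        raise ValueError("stain matrix columns must be linearly independent")
    return m


@dataclass
class StainProfile:
    """A reference stain basis plus per-stain high-percentile
    concentration scales used as the normalization target."""

    stain_matrix: np.ndarray
    concentration_scale: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0])
    )

    def __post_init__(self):
        self.stain_matrix = _validate_matrix(self.stain_matrix)
        self.concentration_scale = np.asarray(self.concentration_scale, dtype=float)
        if self.concentration_scale.shape != (2,) or np.any(
            self.concentration_scale <= 0
        ):
            raise ValueError("concentration_scale must be two positive reals")

    def to_json(self) -> str:
        return json.dumps(
            {
                "stain_matrix": self.stain_matrix.tolist(),
                "concentration_scale": self.concentration_scale.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StainProfile":
        d = json.loads(text)
        return cls(np.array(d["stain_matrix"]), np.array(d["concentration_scale"]))


def default_target_profile() -> StainProfile:
    return StainProfile(DEFAULT_STAIN_MATRIX.copy(), np.array([1.0, 1.0]))


def rgb_to_od(pixels: np.ndarray, background_intensity: float = 1.0,
              eps: float = 1e-6) -> np.ndarray:
    """Beer-Lambert transform: od = -log10(I / I0), clipped at eps so a
    pure-black pixel maps to a large finite OD.  Monotone decreasing in
    pixel intensity; background-bright pixels map to ~0."""
    if background_intensity <= 0:
        raise ValueError("background intensity must be positive")
    pixels = np.asarray(pixels, dtype=float)
    ratio = np.clip(pixels, eps * background_intensity, background_intensity)
    return -np.log10(ratio / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = 1.0) -> np.ndarray:
    """Inverse of rgb_to_od (up to the clipping guard)."""
    if background_intensity <= 0:
        raise ValueError("background intensity must be positive")
    return background_intensity * np.power(10.0, -np.asarray(od, dtype=float))


def estimate_stain_matrix(od: np.ndarray,
                          od_threshold: float = DEFAULT_OD_THRESHOLD,
                          angle_percentile: float = DEFAULT_ANGLE_PERCENTILE,
                          ) -> np.ndarray:
    """Macenko stain-vector estimation from an OD image or pixel list.

    Keeps pixels whose OD magnitude exceeds `od_threshold`, finds the
    two principal directions of the cloud, and takes the directions at
    the `angle_percentile` extremes of the angular distribution in that
    plane.  Columns are unit norm, ordered so the hematoxylin column has
    the larger blue-channel OD.
    """
    if not 0.0 < angle_percentile < 50.0:
        raise ValueError("angle percentile must lie in (0, 50)")
    od = np.asarray(od, dtype=float).reshape(-1, 3)
    keep = od[np.linalg.norm(od, axis=1) > od_threshold]
    if keep.shape[0] < 2:
        raise DegenerateStainError("fewer than 2 pixels above the OD threshold")
    cov = np.cov(keep, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-2] <= 1e-12 * max(evals[-1], 1.0):
        raise DegenerateStainError("OD cloud is rank deficient (single stain)")
    plane = evecs[:, [-1, -2]]  # top-2 principal directions (columns)
    # orient the plane so projections have positive first coordinate
    proj = keep @ plane
    if np.median(proj[:, 0]) < 0:
        plane[:, 0] *= -1
        proj[:, 0] *= -1
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    cols = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        cols.append(v / np.linalg.norm(v))
    v1, v2 = cols
    # hematoxylin convention: larger blue-channel OD first
    if v1[2] >= v2[2]:
        m = np.column_stack([v1, v2])
    else:
        m = np.column_stack([v2, v1])
    return m


def estimate_concentrations(od: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares stain concentrations (clipped at 0) for each pixel.

    od: (..., 3) -> concentrations (..., 2).
    """
    shape = od.shape[:-1]
    flat = np.asarray(od, dtype=float).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(stain_matrix, flat.T, rcond=None)
    return np.clip(conc.T, 0.0, None).reshape(*shape, 2)


def estimate_stain_profile(pixels: np.ndarray,
                           background_intensity: float = 1.0,
                           od_threshold: float = DEFAULT_OD_THRESHOLD,
                           angle_percentile: float = DEFAULT_ANGLE_PERCENTILE,
                           regularization: float = DEFAULT_REGULARIZATION,
                           ) -> StainProfile:
    """Estimate a tile's stain matrix and reference concentration scales
    (99th percentile per stain, floored at `regularization`)."""
    od = rgb_to_od(pixels, background_intensity)
    m = estimate_stain_matrix(od, od_threshold, angle_percentile)
    conc = estimate_concentrations(od, m).reshape(-1, 2)
    scale = np.percentile(conc, CONCENTRATION_PERCENTILE, axis=0)
    scale = np.maximum(scale, regularization)
    return StainProfile(m, scale)


def normalize_stains(pixels: np.ndarray, target: StainProfile | None = None,
                     background_intensity: float = 1.0,
                     od_threshold: float = DEFAULT_OD_THRESHOLD,
                     angle_percentile: float = DEFAULT_ANGLE_PERCENTILE,
                     regularization: float = DEFAULT_REGULARIZATION,
                     ) -> np.ndarray:
    """Re-render a tile's estimated concentrations through the target
    stain profile.  Degenerate tiles (no estimable stains) pass through
    unchanged with a logged warning.
    """
    pixels = np.asarray(pixels, dtype=float)
    if target is None:
        target = default_target_profile()
    try:
        src = estimate_stain_profile(pixels, background_intensity,
                                     od_threshold, angle_percentile,
                                     regularization)
    except DegenerateStainError as err:
        log.warning("stain normalization skipped: %s", err)
        return pixels.copy()
    od = rgb_to_od(pixels, background_intensity)
    conc = estimate_concentrations(od, src.stain_matrix)
    conc = conc * (target.concentration_scale / src.concentration_scale)
    od_new = conc @ target.stain_matrix.T
    out = od_to_rgb(od_new, background_intensity)
    return np.clip(out, 0.0, background_intensity)
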