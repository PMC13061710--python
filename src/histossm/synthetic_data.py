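"""Synthetic H&E-like tile generator with patient structure.

Tiles are rendered through the Beer-Lambert law: two per-pixel
concentration canvases (hematoxylin-like for nuclei, eosin-like for
stroma) are combined through a per-patient stain matrix,
``pixels = 10 ** (-(concentrations @ M.T))``, giving values in (0, 1].

Class morphology: normal tiles contain ring-shaped glands whose nuclei
have low size variance; abnormal tiles contain crowded, irregular
clusters of pleomorphic (high size-variance) nuclei.  Each synthetic
patient gets one jittered stain matrix shared by all of its tiles,
emulating scanner/staining variation between cases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, measure

from .stain_norm import DEFAULT_STAIN_MATRIX

__all__ = [
    "RgbTile", "CohortSpec", "DEFAULT_NORMAL_FRACTION",
    "jitter_stain_matrix", "generate_tile", "generate_cohort",
    "write_cohort", "load_cohort", "nucleus_blob_stats",
]

# composition of the reference archive: 148,120 normal / 245,196 total
DEFAULT_NORMAL_FRACTION = 148120 / 245196


@dataclass
class RgbTile:
    """One tile: float pixels (H, W, 3) in [0, 1], binary label
    (0 = normal, 1 = abnormal), and provenance ids."""

    pixels: np.ndarray
    label: int
    patient_id: str
    tile_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("tiles must be square")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixels must lie in [0, 1]")


@dataclass
class CohortSpec:
    n_patients: int = 20
    tiles_per_patient: int = 10
    normal_fraction: float = DEFAULT_NORMAL_FRACTION
    tile_size: int = 64
    stain_jitter: float = 5.0  # degrees
    seed: int = 0
    single_class_patients: bool = True

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.tiles_per_patient < 1:
            raise ValueError("need at least 1 tile per patient")
        if not 0.0 < self.normal_fraction < 1.0:
            raise ValueError("normal_fraction must lie in (0, 1)")


def jitter_stain_matrix(base: np.ndarray, angle_deg: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Rotate both stain vectors by a random 3-D rotation of angle
    ~ N(0, angle_deg); columns re-normalized, ordering preserved."""
    base = np.asarray(base, dtype=float)
    if angle_deg <= 0:
        return base.copy()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = np.deg2rad(rng.normal(0.0, angle_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
    m = rot @ base
    m = np.abs(m)  # stain vectors live in the nonnegative octant
    m /= np.linalg.norm(m, axis=0, keepdims=True)
    if m[2, 0] < m[2, 1]:  # keep hematoxylin-first (blue) convention
        m = m[:, ::-1]
    return m


def _smooth_noise(shape, sigma, rng):
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma)


def _paint_nucleus(ch, ce, r, c, radius, aspect, angle, rng):
    rr, cc = draw.ellipse(r, c, max(radius, 1.0), max(radius * aspect, 1.0),
                          shape=ch.shape, rotation=angle)
    ch[rr, cc] = 1.25 + 0.15 * rng.random()
    ce[rr, cc] = 0.05


def generate_tile(label: int, patient_stain: np.ndarray,
                  rng: np.random.Generator, tile_size: int = 64) -> np.ndarray:
    """Render one tile's pixel array (H, W, 3) in (0, 1]."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    s = tile_size
    scale = s / 64.0
    # stroma / background canvases
    ce = np.clip(0.35 + 0.25 * _smooth_noise((s, s), s / 8.0, rng), 0.05, 0.9)
    ch = np.clip(0.04 + 0.03 * _smooth_noise((s, s), s / 8.0, rng), 0.0, None)

    if label == 0:
        # regular ring glands, low nucleus-size variance
        n_glands = int(rng.integers(2, 5))
        base_r = 2.2 * scale
        for _ in range(n_glands):
            gr = rng.uniform(0.13, 0.21) * s
            cy = rng.uniform(gr, s - gr)
            cx = rng.uniform(gr, s - gr)
            rr, cc = draw.disk((cy, cx), 0.55 * gr, shape=ce.shape)
            ce[rr, cc] *= 0.12  # lumen
            ch[rr, cc] *= 0.3
            n_nuc = max(8, int(2 * np.pi * gr / (3.0 * base_r)))
            for a in np.linspace(0, 2 * np.pi, n_nuc, endpoint=False):
                aa = a + rng.normal(0, 0.08)
                rad = base_r * (1.0 + rng.normal(0, 0.08))
                _paint_nucleus(ch, ce,
                               cy + gr * np.sin(aa), cx + gr * np.cos(aa),
                               rad, rng.uniform(0.75, 0.9), aa, rng)
    else:
        # irregular crowded clusters, pleomorphic nuclei
        n_clusters = int(rng.integers(3, 6))
        for _ in range(n_clusters):
            cy = rng.uniform(0.15 * s, 0.85 * s)
            cx = rng.uniform(0.15 * s, 0.85 * s)
            n_nuc = int(rng.integers(14, 24))
            for _ in range(n_nuc):
                rad = float(np.exp(rng.normal(np.log(2.6 * scale), 0.45)))
                rad = min(rad, 7.0 * scale)
                _paint_nucleus(ch, ce,
                               cy + rng.normal(0, 0.10 * s),
                               cx + rng.normal(0, 0.10 * s),
                               rad, rng.uniform(0.45, 1.0),
                               rng.uniform(0, np.pi), rng)
        for _ in range(8):  # scattered stray nuclei
            rad = float(np.exp(rng.normal(np.log(2.4 * scale), 0.4)))
            _paint_nucleus(ch, ce, rng.uniform(0, s), rng.uniform(0, s),
                           min(rad, 6.0 * scale), rng.uniform(0.5, 1.0),
                           rng.uniform(0, np.pi), rng)

    conc = np.stack([ch, ce], axis=-1)  # (H, W, 2)
    od = conc @ np.asarray(patient_stain, dtype=float).T
    return np.power(10.0, -od)


def generate_cohort(spec: CohortSpec, render: bool = True,
                    ) -> tuple[list[RgbTile], pd.DataFrame]:
    """Generate tiles and their manifest.

    Each patient receives one jittered stain matrix and (by default) one
    class; the normal/abnormal patient split matches `normal_fraction`
    as closely as whole patients allow.  With render=False the tiles
    carry blank pixel arrays (manifest-only use, e.g. split testing).
    """
    rng = np.random.default_rng(spec.seed)
    n_normal = int(round(spec.n_patients * spec.normal_fraction))
    n_normal = min(max(n_normal, 1), spec.n_patients - 1)
    patient_labels = np.array([0] * n_normal + [1] * (spec.n_patients - n_normal))
    rng.shuffle(patient_labels)
    tiles, rows = [], []
    for i, plabel in enumerate(patient_labels):
        pid = f"P{i:04d}"
        stain = jitter_stain_matrix(DEFAULT_STAIN_MATRIX, spec.stain_jitter, rng)
        for j in range(spec.tiles_per_patient):
            if spec.single_class_patients:
                label = int(plabel)
            else:
                label = int(rng.random() >= spec.normal_fraction)
            tid = f"{pid}_t{j:03d}"
            if render:
                pixels = np.clip(generate_tile(label, stain, rng, spec.tile_size),
                                 0.0, 1.0)
            else:
                pixels = np.full((spec.tile_size, spec.tile_size, 3), 0.5)
            tiles.append(RgbTile(pixels, label, pid, tid))
            rows.append({"tile_id": tid, "patient_id": pid,
                         "label": label, "path": ""})
    return tiles, pd.DataFrame(rows)


def write_cohort(tiles: list[RgbTile], manifest: pd.DataFrame,
                 out_dir: str) -> pd.DataFrame:
    """Write tiles as PNGs plus manifest.csv; returns manifest with paths."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    manifest = manifest.copy()
    for i, tile in enumerate(tiles):
        path = os.path.join(out_dir, f"{tile.tile_id}.png")
        iio.imwrite(path, (tile.pixels * 255.0 + 0.5).astype(np.uint8))
        manifest.loc[manifest.index[i], "path"] = path
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def load_cohort(manifest_path: str) -> tuple[list[RgbTile], pd.DataFrame]:
    import imageio.v3 as iio

    manifest = pd.read_csv(manifest_path)
    tiles = []
    for row in manifest.itertuples():
        pixels = iio.imread(row.path).astype(float) / 255.0
        tiles.append(RgbTile(pixels[:, :, :3], int(row.label),
                             str(row.patient_id), str(row.tile_id)))
    return tiles, manifest


def nucleus_blob_stats(pixels: np.ndarray,
                       threshold: float = 0.55) -> tuple[int, float, float]:
    """Crude nucleus segmentation for sanity baselines: (blob count,
    blob-area variance, mean image intensity)."""
    gray = np.asarray(pixels, dtype=float).mean(axis=-1)
    mask = gray < threshold
    labels = measure.label(mask)
    areas = [r.area for r in measure.regionprops(labels)]
    count = len(areas)
    var = float(np.var(areas)) if areas else 0.0
    return count, var, float(gray.mean())
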