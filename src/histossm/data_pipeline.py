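"""Patient-independent splitting, minority oversampling, augmentation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize as _resize

from .synthetic_data import RgbTile

__all__ = [
    "SplitManifest", "AugmentParams",
    "patient_independent_split", "oversample_minority", "augment",
]

SUBSETS = ("train", "val", "test")


@dataclass
class SplitManifest:
    """Whole-patient assignment to train/val/test."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def patients(self, subset: str) -> set[str]:
        return {p for p, s in self.assignment.items() if s == subset}

    def subset_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"patient_id": p, "subset": s} for p, s in sorted(self.assignment.items())]
        )

    def write_csv(self, path: str):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str, fractions=(0.70, 0.15, 0.15), seed: int = 0):
        df = pd.read_csv(path)
        return cls(dict(zip(df.patient_id.astype(str), df.subset)), tuple(fractions), seed)


def patient_independent_split(manifest: pd.DataFrame,
                              fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                              seed: int = 0) -> SplitManifest:
    """Greedy randomized assignment of whole patients to subsets,
    targeting tile-count fractions.

    Patients are visited in seeded random order; each is assigned to the
    subset with the largest remaining tile deficit.  No patient ever
    appears in two subsets.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    counts = manifest.groupby("patient_id").size()
    patients = list(counts.index.astype(str))
    if len(patients) < len(SUBSETS):
        raise ValueError("need at least as many patients as subsets")
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(patients)))
    deficits = {s: f * total for s, f in zip(SUBSETS, fractions)}
    assignment: dict[str, str] = {}
    for idx in order:
        pid = patients[idx]
        subset = max(SUBSETS, key=lambda s: deficits[s])
        assignment[pid] = subset
        deficits[subset] -= counts.iloc[idx]
    # guarantee every subset with a positive target holds >= 1 patient
    for subset, frac in zip(SUBSETS, fractions):
        if frac > 0 and not any(s == subset for s in assignment.values()):
            donor_subset = max(SUBSETS,
                               key=lambda s: sum(v == s for v in assignment.values()))
            donor = next(p for p, s in assignment.items() if s == donor_subset)
            assignment[donor] = subset
    return SplitManifest(assignment, fractions, seed)


def oversample_minority(items, seed: int = 0):
    """Equalize class counts by duplicating minority samples with
    replacement.  Accepts a DataFrame with a 'label' column or a
    sequence of objects with a .label attribute; majority untouched.
    """
    is_frame = isinstance(items, pd.DataFrame)
    labels = (items["label"].to_numpy() if is_frame
              else np.array([t.label for t in items]))
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to oversample")
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return items.copy() if is_frame else list(items)
    pool = np.flatnonzero(labels == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    if is_frame:
        return pd.concat([items, items.iloc[extra]], ignore_index=True)
    return list(items) + [items[i] for i in extra]


@dataclass
class AugmentParams:
    """Training-time augmentation; any field can be disabled.

    crop_scale: (lo, hi) area-side fraction for random crop-and-resize,
    or None.  rotate: 'ortho' (multiples of 90 degrees), 'any'
    (arbitrary angle, interpolated), or 'none'.
    """

    crop_scale: tuple[float, float] | None = (0.8, 1.0)
    flip_horizontal: float = 0.5
    flip_vertical: float = 0.5
    rotate: str = "ortho"
    noise_std: float = 0.01

    @classmethod
    def none(cls) -> "AugmentParams":
        return cls(crop_scale=None, flip_horizontal=0.0, flip_vertical=0.0,
                   rotate="none", noise_std=0.0)


def augment(tile: RgbTile, rng: np.random.Generator,
            params: AugmentParams | None = None) -> RgbTile:
    """Random crop-and-resize, flips, rotation, and Gaussian noise
    (clipped to [0, 1]); label and patient id are preserved."""
    if params is None:
        params = AugmentParams()
    px = tile.pixels
    size = px.shape[0]
    if params.crop_scale is not None:
        scale = rng.uniform(*params.crop_scale)
        crop = max(2, int(round(size * scale)))
        if crop < size:
            r0 = int(rng.integers(0, size - crop + 1))
            c0 = int(rng.integers(0, size - crop + 1))
            px = _resize(px[r0:r0 + crop, c0:c0 + crop], (size, size, 3),
                         order=1, mode="reflect", anti_aliasing=False)
    if rng.random() < params.flip_horizontal:
        px = px[:, ::-1]
    if rng.random() < params.flip_vertical:
        px = px[::-1]
    if params.rotate == "ortho":
        px = np.rot90(px, k=int(rng.integers(0, 4)))
    elif params.rotate == "any":
        from skimage.transform import rotate as _rot

        px = _rot(px, float(rng.uniform(0, 360)), mode="reflect", order=1)
    elif params.rotate != "none":
        raise ValueError(f"unknown rotation mode {params.rotate!r}")
    if params.noise_std > 0:
        px = px + rng.normal(0.0, params.noise_std, size=px.shape)
    px = np.clip(px, 0.0, 1.0)
    return RgbTile(np.ascontiguousarray(px), tile.label, tile.patient_id,
                   tile.tile_id)
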