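"""Volume preprocessing and cohort partitioning.

Covers intensity min-max normalization to [0, 1], blank-border cropping with
trilinear resizing to a cube, sliding-window cubic patch extraction with its
exact inverse (overlap-averaged reassembly), stratified k-fold partitioning
under the incomplete/complete protocols, and paired flip augmentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import Cohort, Subject, Volume

__all__ = [
    "PatchSet",
    "FoldPlan",
    "DegenerateRangeError",
    "GeometryError",
    "minmax_normalize",
    "crop_resize",
    "extract_patches",
    "reassemble",
    "make_folds",
    "assign_split_tags",
    "augment_flip",
    "augment_flip_pair",
    "normalize_cohort",
]


class DegenerateRangeError(ValueError):
    """Constant volume: min-max normalization is undefined."""


class GeometryError(ValueError):
    """Patch geometry does not tile the volume exactly."""


@dataclass
class PatchSet:
    """Ordered sliding-window grid of cubic patches.

    Origins are 0-based corner coordinates (i, j, k) in the source volume,
    in lexicographic order; the grid covers every offset in
    {0, stride, ..., edge - patch_size} on each axis, so the set suffices
    to reassemble the source exactly.
    """

    patches: list[np.ndarray]
    origins: list[tuple[int, int, int]]
    patch_size: int
    source_shape: int
    modality: str = "MRI"

    def __post_init__(self):
        if len(self.patches) != len(self.origins):
            raise GeometryError("patches and origins must have equal length")

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class FoldPlan:
    k: int
    assignments: dict[str, int]
    protocol: str
    seed: int
    validation_fold: int = field(default=0)

    def to_csv(self, path: str | Path, cohort: Cohort | None = None) -> Path:
        rows = [
            {
                "subject_id": sid,
                "fold": fold,
                "split_tag": (cohort.by_id(sid).split_tag if cohort else ""),
            }
            for sid, fold in sorted(self.assignments.items())
        ]
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


def minmax_normalize(volume: Volume) -> Volume:
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi == lo:
        raise DegenerateRangeError(
            f"constant {volume.modality} volume (value {lo}); cannot min-max normalize"
        )
    data = (volume.data.astype(np.float64) - lo) / (hi - lo)
    return Volume(data, volume.modality, intensity_range=(lo, hi))


def crop_resize(volume: Volume, target_edge: int) -> Volume:
    """Strip all-zero boundary slabs, then trilinearly resize to a cube."""
    data = volume.data
    nz = np.nonzero(data)
    if nz[0].size == 0:
        raise ValueError("all-zero volume: nothing to crop")
    slices = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    box = data[slices].astype(np.float64)
    if box.shape == (target_edge,) * 3:
        return Volume(box, volume.modality, volume.intensity_range)
    factors = [target_edge / s for s in box.shape]
    resized = ndimage.zoom(box, factors, order=1, grid_mode=True, mode="grid-constant")
    if resized.shape != (target_edge,) * 3:  # guard against rounding in zoom
        resized = resized[tuple(slice(0, target_edge) for _ in range(3))]
    return Volume(resized, volume.modality, volume.intensity_range)


def _grid_offsets(edge: int, patch_size: int, stride: int) -> list[int]:
    if patch_size > edge:
        raise GeometryError(f"patch_size {patch_size} exceeds volume edge {edge}")
    if stride <= 0:
        raise GeometryError("stride must be positive")
    span = edge - patch_size
    if span % stride != 0:
        raise GeometryError(
            f"(edge - patch_size) = {span} is not divisible by stride {stride}; "
            "refusing silent truncation"
        )
    return list(range(0, span + 1, stride))


def extract_patches(volume: Volume, patch_size: int, stride: int) -> PatchSet:
    edge = volume.edge
    offsets = _grid_offsets(edge, patch_size, stride)
    origins = list(itertools.product(offsets, repeat=3))
    patches = [
        np.array(
            volume.data[i : i + patch_size, j : j + patch_size, k : k + patch_size]
        )
        for (i, j, k) in origins
    ]
    return PatchSet(
        patches=patches,
        origins=[tuple(o) for o in origins],
        patch_size=patch_size,
        source_shape=edge,
        modality=volume.modality,
    )


def reassemble(patchset: PatchSet) -> Volume:
    """Each voxel is the arithmetic mean of all patch values covering it."""
    edge, p = patchset.source_shape, patchset.patch_size
    total = np.zeros((edge,) * 3, dtype=np.float64)
    count = np.zeros((edge,) * 3, dtype=np.float64)
    for patch, (i, j, k) in zip(patchset.patches, patchset.origins):
        patch = np.asarray(patch)
        if patch.shape != (p,) * 3:
            raise GeometryError(f"patch at {(i, j, k)} has shape {patch.shape}")
        if i + p > edge or j + p > edge or k + p > edge or min(i, j, k) < 0:
            raise GeometryError(f"patch origin {(i, j, k)} outside {edge}^3 volume")
        total[i : i + p, j : j + p, k : k + p] += patch
        count[i : i + p, j : j + p, k : k + p] += 1.0
    if (count == 0).any():
        raise GeometryError("patch grid does not cover the volume")
    return Volume(total / count, patchset.modality)  # type: ignore[arg-type]


def _stratified_folds(
    subjects: list[Subject], k: int, rng: np.random.Generator
) -> dict[str, int]:
    assignments: dict[str, int] = {}
    for label in (0, 1):
        ids = sorted(s.subject_id for s in subjects if s.label == label)
        if len(ids) < k:
            raise ValueError(
                f"class {label} has {len(ids)} subjects, fewer than k={k}; "
                "cannot stratify"
            )
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            assignments[sid] = i % k
    return assignments


def make_folds(cohort: Cohort, k: int, protocol: str, seed: int) -> FoldPlan:
    """Stratified k-subset plan.

    incomplete: only paired subjects are folded; every unpaired subject is
    test. complete: paired and unpaired subjects are pooled into k folds;
    the held-out fold later splits into validation (paired) and test
    (unpaired).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if protocol not in ("incomplete", "complete"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(seed)
    pool = cohort.paired if protocol == "incomplete" else list(cohort.subjects)
    assignments = _stratified_folds(pool, k, rng)
    return FoldPlan(k=k, assignments=assignments, protocol=protocol, seed=seed)


def assign_split_tags(cohort: Cohort, plan: FoldPlan, validation_fold: int = 0) -> Cohort:
    """Tag subjects in place as train/validation/test according to the plan."""
    plan.validation_fold = validation_fold
    for s in cohort.subjects:
        fold = plan.assignments.get(s.subject_id)
        if plan.protocol == "incomplete":
            if fold is None:  # unpaired
                s.split_tag = "test"
            elif fold == validation_fold:
                s.split_tag = "validation"
            else:
                s.split_tag = "train"
        else:  # complete: held-out fold splits by modality availability
            if fold == validation_fold:
                s.split_tag = "validation" if s.has_pet else "test"
            else:
                s.split_tag = "train"
    return cohort


def augment_flip(
    volume: Volume,
    axes: tuple[int, ...] = (0, 1),
    probability: float = 0.5,
    rng: np.random.Generator | None = None,
) -> Volume:
    """Independently flip along each listed axis with the given probability."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    flips = [axis for axis in axes if rng.random() < probability]
    data = np.flip(volume.data, axis=flips).copy() if flips else volume.data.copy()
    return Volume(data, volume.modality, volume.intensity_range)


def augment_flip_pair(
    mri: Volume,
    pet: Volume,
    axes: tuple[int, ...] = (0, 1),
    probability: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, Volume]:
    """Draw flips once and apply them identically to both modalities."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    flips = [axis for axis in axes if rng.random() < probability]

    def apply(v: Volume) -> Volume:
        data = np.flip(v.data, axis=flips).copy() if flips else v.data.copy()
        return Volume(data, v.modality, v.intensity_range)

    return apply(mri), apply(pet)


def normalize_cohort(cohort: Cohort) -> Cohort:
    """Min-max normalize every volume of every subject, in place."""
    for s in cohort.subjects:
        s.mri = minmax_normalize(s.mri)
        if s.pet is not None:
            s.pet = minmax_normalize(s.pet)
        if s.pet_clean is not None:
            s.pet_clean = minmax_normalize(s.pet_clean)
    return cohort
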