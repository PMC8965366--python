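"""Synthetic two-class neuroimaging cohorts with a missing-PET subset.

Emulates the statistical structure the downstream method assumes, without
any real scans: each subject has a cubic "MRI" volume built from smooth
anatomy-like texture; paired subjects additionally have a "PET" volume
produced by a fixed smooth monotone voxelwise map of the MRI, plus a
class-dependent intensity shift confined to designated spherical lesion
regions (the planted diagnostic signal), plus additive Gaussian noise.
A configurable fraction of subjects lacks PET entirely (the unpaired,
MRI-only subset), mirroring cohorts where the second modality is missing.

The noiseless cross-modal map is retained per subject (``pet_clean``) as a
ground-truth oracle for generator tests; it is never serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "Volume",
    "Subject",
    "Cohort",
    "CohortConfigError",
    "CohortIOError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "smoothstep",
    "lesion_mask",
]

Modality = Literal["MRI", "PET"]


class CohortConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


class CohortIOError(IOError):
    """Cohort directory is malformed or incomplete."""


@dataclass
class Volume:
    """A single-modality 3-D intensity array.

    ``intensity_range`` records (min, max) at creation time, before any
    downstream normalization.
    """

    data: np.ndarray
    modality: Modality
    intensity_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic 3-D, got shape {self.data.shape}")
        if self.intensity_range is None:
            self.intensity_range = (float(self.data.min()), float(self.data.max()))

    @property
    def edge(self) -> int:
        return self.data.shape[0]


@dataclass
class Subject:
    subject_id: str
    label: int
    mri: Volume
    pet: Volume | None = None
    pet_clean: Volume | None = None  # ground-truth noiseless PET; in-memory only
    split_tag: str | None = None

    @property
    def has_pet(self) -> bool:
        return self.pet is not None


@dataclass
class Cohort:
    subjects: list[Subject]
    config: "SyntheticConfig | None" = None

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def paired(self) -> list[Subject]:
        return [s for s in self.subjects if s.has_pet]

    @property
    def unpaired(self) -> list[Subject]:
        return [s for s in self.subjects if not s.has_pet]

    def by_id(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def smoothstep(t: np.ndarray) -> np.ndarray:
    """Fixed smooth monotone cross-modal nonlinearity on [0, 1]."""
    return t * t * (3.0 - 2.0 * t)


_CROSSMODAL_FNS = {"smoothstep": smoothstep, "identity": lambda t: t}


def _default_lesions(edge: int) -> list[tuple[tuple[int, int, int], int]]:
    r = max(2, edge // 8)
    quarter, three_q = edge // 4, (3 * edge) // 4
    return [
        ((quarter, quarter, quarter), r),
        ((three_q, three_q, edge // 2), r),
    ]


@dataclass
class SyntheticConfig:
    volume_size: int = 16
    n_paired_per_class: int = 8
    n_unpaired_per_class: int = 4
    smoothness: float = 2.0
    crossmodal_gain: float = 1.0
    crossmodal_offset: float = 0.0
    crossmodal_fn: str = "smoothstep"
    effect_size: float = 0.4
    mri_effect_fraction: float = 0.25
    lesion_regions: list[tuple[tuple[int, int, int], int]] | None = None
    noise_sd: float = 0.05
    missing_label_policy: str = "per_class"  # or "imbalanced" (27:76 split)
    seed: int = 0

    def resolved_lesions(self) -> list[tuple[tuple[int, int, int], int]]:
        return (
            list(self.lesion_regions)
            if self.lesion_regions is not None
            else _default_lesions(self.volume_size)
        )

    def validate(self) -> None:
        if self.volume_size < 4:
            raise CohortConfigError("volume_size must be at least 4 voxels")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise CohortConfigError("effect_size and noise_sd must be non-negative")
        if self.n_paired_per_class < 0 or self.n_unpaired_per_class < 0:
            raise CohortConfigError("subject counts must be non-negative")
        if self.crossmodal_fn not in _CROSSMODAL_FNS:
            raise CohortConfigError(f"unknown crossmodal_fn {self.crossmodal_fn!r}")
        for center, radius in self.resolved_lesions():
            for c in center:
                if c - radius < 0 or c + radius >= self.volume_size:
                    raise CohortConfigError(
                        f"lesion region {center} r={radius} extends outside the "
                        f"{self.volume_size}^3 volume"
                    )


def lesion_mask(edge: int, regions: Iterable[tuple[tuple[int, int, int], int]]) -> np.ndarray:
    """Boolean union of spherical regions on an edge^3 grid."""
    grid = np.indices((edge, edge, edge))
    mask = np.zeros((edge, edge, edge), dtype=bool)
    for center, radius in regions:
        d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
        mask |= d2 <= radius**2
    return mask


def _radial_anatomy(edge: int) -> np.ndarray:
    grid = np.indices((edge, edge, edge)).astype(np.float64)
    c = (edge - 1) / 2.0
    r = np.sqrt(sum((grid[a] - c) ** 2 for a in range(3)))
    return np.clip(1.0 - r / (edge / 2.0), 0.0, 1.0)


def _background(rng: np.random.Generator, edge: int, smoothness: float) -> np.ndarray:
    """Gaussian-smoothed white noise blended with a radial anatomy gradient."""
    texture = ndimage.gaussian_filter(rng.standard_normal((edge, edge, edge)), smoothness)
    lo, hi = texture.min(), texture.max()
    if hi > lo:
        texture = (texture - lo) / (hi - lo)
    return 0.55 * _radial_anatomy(edge) + 0.45 * texture


def _make_subject(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    subject_id: str,
    label: int,
    with_pet: bool,
    mask: np.ndarray,
) -> Subject:
    g = _CROSSMODAL_FNS[cfg.crossmodal_fn]
    mri = _background(rng, cfg.volume_size, cfg.smoothness)
    if label == 1 and cfg.effect_size > 0:
        mri = mri + cfg.mri_effect_fraction * cfg.effect_size * mask
    mri = np.clip(mri, 0.0, 1.0)

    pet_clean = cfg.crossmodal_gain * g(mri) + cfg.crossmodal_offset
    if label == 1 and cfg.effect_size > 0:
        pet_clean = pet_clean + cfg.effect_size * mask
    noise = rng.normal(0.0, cfg.noise_sd, mri.shape) if cfg.noise_sd > 0 else 0.0
    pet = pet_clean + noise

    return Subject(
        subject_id=subject_id,
        label=label,
        mri=Volume(mri, "MRI"),
        pet=Volume(pet, "PET") if with_pet else None,
        pet_clean=Volume(pet_clean, "PET"),
    )


def _unpaired_counts(cfg: SyntheticConfig) -> tuple[int, int]:
    total = 2 * cfg.n_unpaired_per_class
    if cfg.missing_label_policy == "per_class":
        return cfg.n_unpaired_per_class, cfg.n_unpaired_per_class
    if cfg.missing_label_policy == "imbalanced":
        # mirror a 27:76 EMCI:LMCI split of the MRI-only pool
        n0 = int(round(total * 27 / 103))
        return n0, total - n0
    raise CohortConfigError(f"unknown missing_label_policy {cfg.missing_label_policy!r}")


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Deterministically generate a paired + MRI-only cohort.

    Identical (config, seed) pairs produce bit-identical cohorts: each
    subject draws from its own child stream of a single seed sequence.
    """
    config.validate()
    mask = lesion_mask(config.volume_size, config.resolved_lesions()).astype(np.float64)
    root = np.random.SeedSequence(config.seed)

    plan: list[tuple[str, int, bool]] = []
    for label in (0, 1):
        for i in range(config.n_paired_per_class):
            plan.append((f"P{label}{i:03d}", label, True))
    n0, n1 = _unpaired_counts(config)
    for label, count in ((0, n0), (1, n1)):
        for i in range(count):
            plan.append((f"U{label}{i:03d}", label, False))

    subjects = [
        _make_subject(config, np.random.default_rng(child), sid, label, with_pet, mask)
        for (sid, label, with_pet), child in zip(plan, root.spawn(len(plan)))
    ]
    return Cohort(subjects=subjects, config=replace(config))


# ---------------------------------------------------------------------------
# NIfTI + manifest I/O
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.csv"


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """One .nii.gz per volume plus a CSV manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        mri_path = f"{s.subject_id}_mri.nii.gz"
        nib.save(nib.Nifti1Image(s.mri.data, np.eye(4)), directory / mri_path)
        pet_path = ""
        if s.pet is not None:
            pet_path = f"{s.subject_id}_pet.nii.gz"
            nib.save(nib.Nifti1Image(s.pet.data, np.eye(4)), directory / pet_path)
        rows.append(
            {
                "subject_id": s.subject_id,
                "label": s.label,
                "has_pet": s.pet is not None,
                "mri_path": mri_path,
                "pet_path": pet_path,
            }
        )
    manifest = directory / _MANIFEST
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _load_volume(directory: Path, rel_path: str, modality: Modality, sid: str) -> Volume:
    path = directory / rel_path
    if not path.exists():
        raise CohortIOError(f"missing {modality} file for subject {sid}: {path}")
    img = nib.load(path)
    return Volume(np.asarray(img.dataobj, dtype=np.float32), modality)


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    manifest = directory / _MANIFEST
    if not manifest.exists():
        raise CohortIOError(f"no manifest at {manifest}")
    df = pd.read_csv(manifest, keep_default_na=False)
    required = {"subject_id", "label", "has_pet", "mri_path", "pet_path"}
    if not required.issubset(df.columns):
        raise CohortIOError(f"manifest missing columns {sorted(required - set(df.columns))}")
    subjects = []
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        mri = _load_volume(directory, row.mri_path, "MRI", sid)
        pet = None
        if str(row.has_pet) in ("True", "true", "1"):
            pet = _load_volume(directory, row.pet_path, "PET", sid)
        subjects.append(Subject(subject_id=sid, label=int(row.label), mri=mri, pet=pet))
    return Cohort(subjects=subjects)
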