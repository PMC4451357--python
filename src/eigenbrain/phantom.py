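"""Synthetic registered brain-like volume generator.

Produces a cohort of co-registered 3D volumes sharing a smooth template
(a bright ellipsoidal shell around a dark interior cavity, standing in for
cortex and ventricle), with class-dependent additive mean shifts inside
configurable spherical effect regions and i.i.d. Gaussian voxel noise.
The ground-truth mask of affected voxels is returned alongside, so every
downstream stage can be validated without external imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "EffectRegion",
    "PhantomConfig",
    "PhantomTruth",
    "LabeledVolumeSet",
    "generate_phantom",
    "write_dataset",
]


@dataclass(frozen=True)
class EffectRegion:
    """Spherical region whose mean intensity differs between classes.

    ``magnitude`` is added to the expected intensity of every disease-class
    (label 1) voxel inside the ball of ``radius`` voxels around ``center``.
    """

    center: tuple[int, int, int]
    radius: float
    magnitude: float


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of the synthetic cohort.

    Attributes
    ----------
    shape : tuple of int
        Volume shape in voxels.
    coronal_axis : int
        Array axis treated as the coronal (slice-selection) axis.
    n_nc, n_ad : int
        Number of control (label 0) and disease (label 1) subjects.
    effect_regions : sequence of EffectRegion
        Class-contrast regions applied to the disease class only.
    noise_sd : float
        Standard deviation of the i.i.d. Gaussian voxel noise.
    baseline_intensity : float
        Peak intensity of the template shell.
    seed : int
        RNG seed; generation is fully deterministic given the config.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    coronal_axis: int = 0
    n_nc: int = 10
    n_ad: int = 10
    effect_regions: tuple[EffectRegion, ...] = ()
    noise_sd: float = 1.0
    baseline_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ConfigurationError(f"shape must be 3 positive ints, got {self.shape}")
        if not 0 <= self.coronal_axis <= 2:
            raise ConfigurationError("coronal_axis must be 0, 1, or 2")
        if self.n_nc < 2 or self.n_ad < 2:
            raise ConfigurationError("need at least 2 subjects per class")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for reg in self.effect_regions:
            c = np.asarray(reg.center, dtype=float)
            if c.shape != (3,):
                raise ConfigurationError(f"effect center must be 3D, got {reg.center}")
            lo = c - reg.radius
            hi = c + reg.radius
            if (lo < 0).any() or (hi > np.asarray(self.shape) - 1).any():
                raise ConfigurationError(
                    f"effect region {reg} does not fit inside shape {self.shape}"
                )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth: boolean mask of voxels with nonzero expected class contrast."""

    effect_mask: np.ndarray

    def __post_init__(self):
        if self.effect_mask.dtype != bool:
            object.__setattr__(self, "effect_mask", self.effect_mask.astype(bool))


@dataclass
class LabeledVolumeSet:
    """A cohort of registered volumes with binary diagnosis labels.

    ``labels`` uses 0 for controls and 1 for the disease class.
    """

    volumes: np.ndarray  # (N, *shape)
    labels: np.ndarray  # (N,) in {0, 1}
    subject_ids: list[str]
    coronal_axis: int = 0

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.volumes.ndim != 4:
            raise ConfigurationError("volumes must be a 4D (N, X, Y, Z) array")
        n = self.volumes.shape[0]
        if self.labels.shape != (n,) or len(self.subject_ids) != n:
            raise ConfigurationError("volumes, labels and subject_ids must align")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ConfigurationError("labels must be binary (0=control, 1=disease)")

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]


def _template(shape: tuple[int, int, int], peak: float) -> np.ndarray:
    """Smooth ellipsoidal shell with an interior cavity.

    Intensity profile along the normalized ellipsoidal radius r:
    bright shell near r ~ 0.75, dark cavity at the center, zero outside r > 1.
    """
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij"
    )
    # slightly anisotropic semi-axes so no axis is degenerate
    semi = (0.92, 0.85, 0.78)
    r = np.sqrt(sum((g / a) ** 2 for g, a in zip(grids, semi)))
    inside = r <= 1.0
    shell = np.exp(-(((r - 0.72) / 0.28) ** 2))  # cortex-like bright band
    cavity = np.exp(-((r / 0.28) ** 2))  # central ventricle-like dark zone
    tissue = 0.55 + 0.45 * shell - 0.5 * cavity
    return peak * np.where(inside, tissue, 0.0)


def _ball_mask(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    c = np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    return ((idx - c) ** 2).sum(axis=0) <= radius**2


def effect_field(config: PhantomConfig) -> np.ndarray:
    """Expected disease-minus-control intensity difference per voxel."""
    field_ = np.zeros(config.shape, dtype=float)
    for reg in config.effect_regions:
        field_ += reg.magnitude * _ball_mask(config.shape, reg.center, reg.radius)
    return field_


def generate_phantom(config: PhantomConfig) -> tuple[LabeledVolumeSet, PhantomTruth]:
    """Generate the cohort described by ``config``.

    Control subjects are template + noise; disease subjects additionally get
    the effect field. Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    template = _template(config.shape, config.baseline_intensity)
    contrast = effect_field(config)
    n = config.n_nc + config.n_ad
    labels = np.concatenate(
        [np.zeros(config.n_nc, dtype=int), np.ones(config.n_ad, dtype=int)]
    )
    volumes = np.empty((n,) + tuple(config.shape), dtype=float)
    for i, lab in enumerate(labels):
        mean = template + contrast if lab == 1 else template
        volumes[i] = mean + rng.normal(0.0, config.noise_sd, size=config.shape)
    ids = [f"sub-{i:04d}" for i in range(n)]
    truth = PhantomTruth(effect_mask=contrast != 0)
    return (
        LabeledVolumeSet(
            volumes=volumes,
            labels=labels,
            subject_ids=ids,
            coronal_axis=config.coronal_axis,
        ),
        truth,
    )


def write_dataset(dataset: LabeledVolumeSet, out_dir: str | Path) -> Path:
    """Write one NIfTI per subject plus a ``labels.csv`` (subject_id, cdr, label)."""
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for sid, vol in zip(dataset.subject_ids, dataset.volumes):
        # float64 on disk so a written cohort round-trips bit-exactly
        nib.save(nib.Nifti1Image(vol, affine), out / f"{sid}.nii")
    table = pd.DataFrame(
        {
            "subject_id": dataset.subject_ids,
            "cdr": dataset.labels,  # label 1 corresponds to CDR 1, label 0 to CDR 0
            "label": dataset.labels,
        }
    )
    table.to_csv(out / "labels.csv", index=False)
    return out
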