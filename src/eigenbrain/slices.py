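"""Coronal slice scoring by inter-class variance and key-slice selection.

A slice's score is the squared Euclidean norm of the difference between the
two class-mean images of that slice. Key slices are those scoring at least a
fraction (default 50%) of the maximum, thinned by a fixed stride (default
every 10th), anchored at the first qualifying slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, SingleClassError
from .phantom import LabeledVolumeSet

__all__ = [
    "ICVProfile",
    "KeySliceSelection",
    "SliceStack",
    "compute_icv",
    "select_key_slices",
    "extract_slices",
]


@dataclass(frozen=True)
class ICVProfile:
    """Per-slice inter-class variance values along one axis (0-based indices)."""

    v: np.ndarray
    axis: int
    norm: str = "squared"  # "squared" or "plain" Euclidean norm

    def __post_init__(self):
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if (self.v < 0).any():
            raise ConfigurationError("ICV values must be nonnegative")

    def __len__(self) -> int:
        return len(self.v)


@dataclass(frozen=True)
class KeySliceSelection:
    key_indices: tuple[int, ...]
    fraction: float
    undersample: int
    axis: int


@dataclass
class SliceStack:
    """All subjects' 2D images at one key slice, in subject order."""

    images: np.ndarray  # (N, H, W)
    key_index: int
    axis: int
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.images.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


def compute_icv(
    dataset: LabeledVolumeSet, axis: int | None = None, norm: str = "squared"
) -> ICVProfile:
    """Score every slice along ``axis`` by the inter-class variance.

    v(k) = || mean_disease(slice k) - mean_control(slice k) ||^2 by default
    (``norm="squared"``); ``norm="plain"`` takes the unsquared norm instead.
    """
    if axis is None:
        axis = dataset.coronal_axis
    if norm not in ("squared", "plain"):
        raise ConfigurationError(f"unknown icv norm {norm!r}")
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise SingleClassError("inter-class variance requires both classes")
    mean_ad = dataset.volumes[labels == 1].mean(axis=0)
    mean_nc = dataset.volumes[labels == 0].mean(axis=0)
    diff2 = (mean_ad - mean_nc) ** 2
    sum_axes = tuple(a for a in range(3) if a != axis)
    v = diff2.sum(axis=sum_axes)
    if norm == "plain":
        v = np.sqrt(v)
    return ICVProfile(v=v, axis=axis, norm=norm)


def select_key_slices(
    profile: ICVProfile, fraction: float = 0.5, undersample: int = 10
) -> KeySliceSelection:
    """Threshold at ``fraction * max(v)`` then take every ``undersample``-th
    candidate, anchored at the smallest candidate index."""
    if len(profile) == 0:
        raise ConfigurationError("empty ICV profile")
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    if undersample < 1:
        raise ConfigurationError("undersample must be >= 1")
    vmax = profile.v.max()
    if vmax == 0:
        raise DegenerateInputError("all-zero ICV profile: threshold undefined")
    candidates = np.flatnonzero(profile.v >= fraction * vmax)
    anchor = int(candidates[0])
    cand = set(candidates.tolist())
    keys = tuple(
        k for k in range(anchor, int(candidates[-1]) + 1, undersample) if k in cand
    )
    return KeySliceSelection(
        key_indices=keys, fraction=fraction, undersample=undersample, axis=profile.axis
    )


def extract_slices(
    dataset: LabeledVolumeSet, selection: KeySliceSelection
) -> list[SliceStack]:
    """Pull the selected planes out of every subject volume, unmodified."""
    extent = dataset.shape[selection.axis]
    stacks = []
    for k in selection.key_indices:
        if not 0 <= k < extent:
            raise ConfigurationError(
                f"slice index {k} out of range for axis extent {extent}"
            )
        images = np.take(dataset.volumes, k, axis=selection.axis + 1)
        stacks.append(
            SliceStack(
                images=images.copy(),
                key_index=int(k),
                axis=selection.axis,
                subject_ids=list(dataset.subject_ids),
            )
        )
    return stacks
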