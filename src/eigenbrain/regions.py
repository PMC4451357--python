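"""Discriminant-voxel detection from the most important eigenbrain.

Per key slice the MIE loading image is rectified (absolute value), the 0.98
quantile of the configured pixel population is taken as a threshold, and
strictly-greater pixels are highlighted. Highlighted pixels can be counted
against a user-supplied integer label volume, or scored against a phantom's
ground-truth effect mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .eigen import EigenbrainSet, reshape_eigenbrain
from .phantom import PhantomTruth

__all__ = [
    "SliceRegions",
    "RegionMap",
    "detect_regions",
    "map_labels",
    "overlap_score",
]


@dataclass
class SliceRegions:
    """Highlighted pixels of one key slice."""

    key_index: int
    threshold: float
    pixel_coords: np.ndarray  # (M, 2) (row, col), 0-based
    voxel_coords: np.ndarray  # (M, 3) with the slice index reinserted, 0-based

    @property
    def count(self) -> int:
        return self.pixel_coords.shape[0]


@dataclass
class RegionMap:
    """Per-slice highlighted voxels plus the quantile used."""

    slices: list[SliceRegions]
    quantile: float
    axis: int
    volume_shape: tuple[int, int, int] | None = None

    @property
    def total_count(self) -> int:
        return sum(s.count for s in self.slices)

    def all_voxel_coords(self) -> np.ndarray:
        if not self.slices:
            return np.zeros((0, 3), dtype=int)
        return np.vstack([s.voxel_coords for s in self.slices])

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table of highlighted voxel coordinates (1-based)."""
        rows = []
        for s in self.slices:
            for (r, c), v in zip(s.pixel_coords, s.voxel_coords):
                rows.append(
                    {
                        "key_slice": s.key_index + 1,
                        "row": r + 1,
                        "col": c + 1,
                        "x": v[0] + 1,
                        "y": v[1] + 1,
                        "z": v[2] + 1,
                        "threshold": s.threshold,
                    }
                )
        return pd.DataFrame(
            rows, columns=["key_slice", "row", "col", "x", "y", "z", "threshold"]
        )


def _insert_axis(pixel_coords: np.ndarray, key_index: int, axis: int) -> np.ndarray:
    out = np.empty((pixel_coords.shape[0], 3), dtype=int)
    other = [a for a in range(3) if a != axis]
    out[:, axis] = key_index
    out[:, other[0]] = pixel_coords[:, 0]
    out[:, other[1]] = pixel_coords[:, 1]
    return out


def detect_regions(
    eigen_sets: list[EigenbrainSet],
    mie_index: int,
    quantile: float = 0.98,
    mask: np.ndarray | None = None,
) -> RegionMap:
    """Highlight per-slice MIE pixels whose |loading| strictly exceeds the
    population quantile (linear-interpolation estimator).

    ``mask`` optionally restricts the quantile population (and the
    highlighted set) to a 2D boolean pixel mask; default is all pixels.
    """
    if not 0 < quantile < 1:
        raise ConfigurationError("quantile must lie strictly inside (0, 1)")
    if not eigen_sets:
        raise DataError("need at least one key slice")
    out = []
    axis = eigen_sets[0].axis
    for es in eigen_sets:
        img = np.abs(reshape_eigenbrain(es, mie_index))
        if mask is not None:
            if mask.shape != img.shape:
                raise DataError("mask shape does not match the slice image")
            population = img[mask]
        else:
            population = img.ravel()
        thr = float(np.quantile(population, quantile))
        hot = img > thr
        if mask is not None:
            hot &= mask
        pix = np.argwhere(hot)
        out.append(
            SliceRegions(
                key_index=es.key_index,
                threshold=thr,
                pixel_coords=pix,
                voxel_coords=_insert_axis(pix, es.key_index, axis),
            )
        )
    return RegionMap(slices=out, quantile=quantile, axis=axis)


def map_labels(
    region_map: RegionMap, label_volume: np.ndarray, background: int = 0
) -> pd.DataFrame:
    """Count highlighted voxels per label, sorted descending; background excluded."""
    label_volume = np.asarray(label_volume)
    if label_volume.ndim != 3:
        raise DataError("label volume must be 3D")
    coords = region_map.all_voxel_coords()
    if coords.size and (
        (coords >= np.asarray(label_volume.shape)).any() or (coords < 0).any()
    ):
        raise DataError("label volume does not cover the highlighted coordinates")
    if coords.size == 0:
        return pd.DataFrame(columns=["label", "n_voxels"])
    labs = label_volume[coords[:, 0], coords[:, 1], coords[:, 2]]
    labs = labs[labs != background]
    values, counts = np.unique(labs, return_counts=True)
    table = pd.DataFrame({"label": values, "n_voxels": counts})
    return table.sort_values("n_voxels", ascending=False, ignore_index=True)


def overlap_score(
    region_map: RegionMap, truth: PhantomTruth
) -> tuple[float, float, float]:
    """(dice, recall, precision) of highlighted voxels vs the ground-truth
    effect mask, restricted to the key slices actually examined."""
    mask = truth.effect_mask
    if region_map.volume_shape is not None and mask.shape != region_map.volume_shape:
        raise DataError("truth shape does not match the analyzed volumes")
    keys = [s.key_index for s in region_map.slices]
    truth_in_keys = np.zeros_like(mask)
    for k in keys:
        sl = [slice(None)] * 3
        sl[region_map.axis] = k
        truth_in_keys[tuple(sl)] = mask[tuple(sl)]
    n_truth = int(truth_in_keys.sum())
    if mask.sum() == 0:
        raise DataError("empty ground-truth mask")
    highlighted = np.zeros_like(mask)
    coords = region_map.all_voxel_coords()
    if coords.size:
        highlighted[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    inter = int((highlighted & truth_in_keys).sum())
    n_high = int(highlighted.sum())
    dice = 2.0 * inter / (n_high + n_truth) if (n_high + n_truth) else 0.0
    recall = inter / n_truth if n_truth else float("nan")
    precision = inter / n_high if n_high else float("nan")
    return dice, recall, precision
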