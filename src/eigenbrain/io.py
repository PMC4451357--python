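"""Dataset readers and artifact writers (NIfTI volumes, CSV/JSON/TSV tables)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError
from .phantom import LabeledVolumeSet

__all__ = [
    "read_dataset",
    "read_label_volume",
    "write_icv_profile",
    "write_selection",
    "write_scores",
    "write_wtt_table",
    "write_cv_report",
    "write_region_map",
    "write_region_mask",
]


def _labels_from_csv(labels_path: Path) -> pd.DataFrame:
    table = pd.read_csv(labels_path)
    if "subject_id" not in table.columns:
        raise DataError(f"{labels_path}: missing 'subject_id' column")
    if "label" in table.columns:
        lab = table["label"]
    elif "cdr" in table.columns:
        cdr = table["cdr"]
        bad = table.loc[~cdr.isin([0, 1]), "subject_id"].tolist()
        if bad:
            raise DataError(
                f"{labels_path}: CDR must be 0 (control) or 1 (disease); "
                f"offending subjects: {bad}"
            )
        lab = cdr
    else:
        raise DataError(f"{labels_path}: need a 'label' or 'cdr' column")
    lab = lab.astype(int)
    if not lab.isin([0, 1]).all():
        bad = table.loc[~lab.isin([0, 1]), "subject_id"].tolist()
        raise DataError(f"{labels_path}: labels must be 0/1; offending: {bad}")
    return pd.DataFrame({"subject_id": table["subject_id"].astype(str), "label": lab})


def read_dataset(
    volumes_path: str | Path, labels_path: str | Path, coronal_axis: int = 0
) -> LabeledVolumeSet:
    """Load per-subject NIfTI volumes joined to a labels CSV by subject id.

    ``volumes_path`` is a directory of ``<subject_id>.nii[.gz]`` files or a
    single 4D NIfTI (subjects along the last axis, CSV row order). The CSV
    needs ``subject_id`` plus ``cdr`` (0/1) or ``label``.
    """
    volumes_path = Path(volumes_path)
    labels_path = Path(labels_path)
    if not labels_path.exists():
        raise DataError(f"labels file not found: {labels_path}")
    labels = _labels_from_csv(labels_path).sort_values("subject_id", ignore_index=True)

    if volumes_path.is_dir():
        files = {}
        for pattern in ("*.nii", "*.nii.gz"):
            for f in volumes_path.glob(pattern):
                files[f.name.removesuffix(".gz").removesuffix(".nii")] = f
        missing = [s for s in labels["subject_id"] if s not in files]
        if missing:
            raise DataError(f"no volume file for subjects: {missing}")
        vols = []
        for sid in labels["subject_id"]:
            vols.append(np.asarray(nib.load(files[sid]).get_fdata(), dtype=float))
        shapes = {v.shape for v in vols}
        if len(shapes) > 1:
            raise DataError(f"subject volumes disagree in shape: {sorted(shapes)}")
        volumes = np.stack(vols)
    else:
        img = nib.load(volumes_path)
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 4:
            raise DataError("single-file input must be a 4D NIfTI")
        if data.shape[3] != len(labels):
            raise DataError(
                f"4D volume has {data.shape[3]} subjects but CSV lists {len(labels)}"
            )
        volumes = np.moveaxis(data, 3, 0)

    return LabeledVolumeSet(
        volumes=volumes,
        labels=labels["label"].to_numpy(),
        subject_ids=labels["subject_id"].tolist(),
        coronal_axis=coronal_axis,
    )


def read_label_volume(path: str | Path) -> np.ndarray:
    vol = np.asarray(nib.load(Path(path)).get_fdata())
    return np.rint(vol).astype(int)


def write_icv_profile(profile, path: str | Path) -> None:
    pd.DataFrame(
        {"slice_index": np.arange(1, len(profile.v) + 1), "icv": profile.v}
    ).to_csv(path, index=False)


def write_selection(selection, path: str | Path, meta: dict | None = None) -> None:
    payload = {
        "key_indices": [int(k) + 1 for k in selection.key_indices],  # 1-based
        "fraction": selection.fraction,
        "undersample": selection.undersample,
        "axis": selection.axis,
    }
    if meta:
        payload.update(meta)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_scores(eigen_sets, path: str | Path) -> None:
    frames = []
    for es in eigen_sets:
        df = pd.DataFrame(
            es.scores,
            columns=[f"eig{j + 1}" for j in range(es.n_eig)],
        )
        df.insert(0, "subject_id", es.subject_ids)
        df.insert(1, "key_slice", es.key_index + 1)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_wtt_table(wtt, path: str | Path) -> None:
    wtt.to_frame().to_csv(path, index=False)


def write_cv_report(report, path: str | Path, meta: dict | None = None) -> None:
    payload = {
        "kernel": report.spec.kind,
        "spec": {
            "C": report.spec.C,
            "sigma": report.spec.sigma,
            "degree": report.spec.degree,
            "coef0": report.spec.coef0,
        },
        "n_folds": report.n_folds,
        "n_reps": report.n_reps,
        "seed": report.seed,
        "confusion": {
            "tp": report.tp.tolist(),
            "fp": report.fp.tolist(),
            "tn": report.tn.tolist(),
            "fn": report.fn.tolist(),
        },
        "metrics_percent": {
            name: {"mean": row["mean"], "sd": row["sd"]}
            for name, row in report.summary(percent=True).iterrows()
        },
    }
    if meta:
        payload.update(meta)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_region_map(region_map, path: str | Path) -> None:
    region_map.to_frame().to_csv(path, sep="\t", index=False)


def write_region_mask(region_map, shape, path: str | Path) -> None:
    mask = np.zeros(shape, dtype=np.uint8)
    coords = region_map.all_voxel_coords()
    if coords.size:
        mask[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
    nib.save(nib.Nifti1Image(mask, np.eye(4)), Path(path))
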