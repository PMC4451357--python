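"""End-to-end pipeline: slice selection -> eigenimages -> MIE -> CV + regions."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as ebio
from .errors import StageError
from .eigen import decompose_stacks
from .mie import build_features, select_mie
from .phantom import LabeledVolumeSet
from .regions import detect_regions
from .slices import compute_icv, extract_slices, select_key_slices
from .svm import KernelSpec, PSOConfig, cross_validate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, serializable to/from YAML."""

    volumes_path: str | None = None
    labels_path: str | None = None
    out_dir: str | None = None
    coronal_axis: int = 0
    icv_fraction: float = 0.5
    icv_undersample: int = 10
    icv_norm: str = "squared"
    standardize_mode: str = "voxel"
    max_rank: int = 6
    alpha: float = 0.05
    kernel: str = "pol"
    n_folds: int = 10
    reps: int = 50
    quantile: float = 0.98
    seed: int = 0
    tune: bool = False
    nested: bool = True
    pso: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    icv_profile: object
    selection: object
    eigen_sets: list
    mie_index: int
    wtt: object
    features: object
    cv_report: object
    region_map: object


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(name, exc) from exc


def run_pipeline(
    config: PipelineConfig, dataset: LabeledVolumeSet | None = None
) -> PipelineResult:
    """Run the full pipeline and (optionally) write all artifacts.

    If ``dataset`` is None it is read from the configured paths. Output files
    embed the config hash and seed so a run can be reproduced exactly.
    """
    if dataset is None:
        dataset = _stage(
            "read_dataset",
            ebio.read_dataset,
            config.volumes_path,
            config.labels_path,
            coronal_axis=config.coronal_axis,
        )

    profile = _stage(
        "icv", compute_icv, dataset, axis=config.coronal_axis, norm=config.icv_norm
    )
    selection = _stage(
        "key_slices",
        select_key_slices,
        profile,
        fraction=config.icv_fraction,
        undersample=config.icv_undersample,
    )
    stacks = _stage("extract_slices", extract_slices, dataset, selection)
    eigen_sets = _stage(
        "eigenbrains", decompose_stacks, stacks, mode=config.standardize_mode
    )
    mie_index, wtt = _stage(
        "mie",
        select_mie,
        eigen_sets,
        dataset.labels,
        alpha=config.alpha,
        max_rank=config.max_rank,
    )
    features = _stage("features", build_features, eigen_sets, mie_index)
    tune = PSOConfig(**config.pso, seed=config.seed) if config.tune else None
    cv_report = _stage(
        "cross_validate",
        cross_validate,
        features.X,
        dataset.labels,
        KernelSpec(kind=config.kernel),
        n_folds=config.n_folds,
        reps=config.reps,
        seed=config.seed,
        tune=tune,
        nested=config.nested,
    )
    region_map = _stage(
        "regions", detect_regions, eigen_sets, mie_index, quantile=config.quantile
    )
    region_map.volume_shape = dataset.shape

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": config.config_hash(), "seed": config.seed}
        config.to_yaml(out / "config.yaml")
        ebio.write_icv_profile(profile, out / "icv.csv")
        ebio.write_selection(selection, out / "key_slices.json", meta=meta)
        ebio.write_scores(eigen_sets, out / "scores.csv")
        ebio.write_wtt_table(wtt, out / "wtt.csv")
        ebio.write_cv_report(cv_report, out / "cv_report.json", meta=meta)
        ebio.write_region_map(region_map, out / "regions.tsv")
        ebio.write_region_mask(region_map, dataset.shape, out / "region_mask.nii")

    return PipelineResult(
        icv_profile=profile,
        selection=selection,
        eigen_sets=eigen_sets,
        mie_index=mie_index,
        wtt=wtt,
        features=features,
        cv_report=cv_report,
        region_map=region_map,
    )
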