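"""End-to-end reproducible pipeline: synth -> preprocess -> train/eval -> saliency.

A run is fully determined by its :class:`RunConfig` plus seed; every run
directory carries a provenance manifest (config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .network import ArchitectureSpec, ResponseNet
from .preprocessing import ClinicalNormalizer
from .saliency import grad_cam, overlay, save_map_nifti, save_overlay
from .synthetic_cohort import ClassImagingParams, CohortConfig, generate_cohort
from .training import (
    MetricsReport,
    TrainingConfig,
    cross_validate,
    dataset_from_cohort,
    train_model,
)


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec.small)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    save_volumes: bool = False
    n_saliency_examples: int = 3

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "cohort": dataclasses.asdict(self.cohort),
            "architecture": self.architecture.to_dict(),
            "training": self.training.to_dict(),
            "save_volumes": self.save_volumes,
            "n_saliency_examples": self.n_saliency_examples,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            for key in ("class1", "class2"):
                if key in c and isinstance(c[key], dict):
                    p = dict(c[key])
                    for t in ("axes_mm", "visible_slices"):
                        if t in p:
                            p[t] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                                         for v in p[t]) if t == "axes_mm" else tuple(p[t])
                    c[key] = ClassImagingParams(**p)
            for t in ("lesions_per_patient", "train_counts", "volume_shape"):
                if t in c:
                    c[t] = tuple(c[t])
            d["cohort"] = CohortConfig(**c)
        if "architecture" in d:
            d["architecture"] = ArchitectureSpec.from_dict(d["architecture"])
        if "training" in d:
            t = dict(d["training"])
            if "downsample" in t:
                t["downsample"] = tuple(t["downsample"])
            d["training"] = TrainingConfig(**t)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ResponseNet, path) -> None:
    spec_json = json.dumps(model.spec.to_dict(), sort_keys=True)
    spec_hash = hashlib.sha256(spec_json.encode()).hexdigest()
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(str(path), __spec__=np.array(spec_json), __spec_hash__=np.array(spec_hash), **arrays)


def load_checkpoint(path) -> ResponseNet:
    try:
        with np.load(str(path), allow_pickle=False) as data:
            spec_json = str(data["__spec__"])
            spec_hash = str(data["__spec_hash__"])
            if hashlib.sha256(spec_json.encode()).hexdigest() != spec_hash:
                raise ValueError("spec hash mismatch")
            state = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise RuntimeError(f"corrupted or incompatible checkpoint {path}: {exc}") from exc
    model = ResponseNet(ArchitectureSpec.from_dict(json.loads(spec_json)))
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir) -> pathlib.Path:
    """Execute the full pipeline into ``out_dir`` and return that path.

    Artifacts: cohort.csv (+ volumes if requested), metrics.json (per-fold
    and mean +- SD), model.npz checkpoint, saliency PNGs/NIfTI, and
    manifest.json with config hash and package version.  Existing
    cohort/metrics artifacts from an earlier partial run are reused.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    cohort = generate_cohort(config.cohort, seed=config.seed)
    cohort_csv = out / "cohort.csv"
    if not cohort_csv.exists():
        cohort.to_dataframe().to_csv(cohort_csv, index=False)
        if config.save_volumes:
            cohort.save(out)

    dataset = dataset_from_cohort(cohort, downsample=config.training.downsample)

    metrics_path = out / "metrics.json"
    if metrics_path.exists():
        report = MetricsReport(**json.loads(metrics_path.read_text()))
    else:
        report = cross_validate(dataset, config.architecture, config.training)
        metrics_path.write_text(json.dumps(report.to_dict(), indent=2))

    # final model on the train_val split, evaluated on held-out test lesions
    split = cohort.split
    train_idx = np.array([i for i, lid in enumerate(dataset.lesion_ids)
                          if split[lid] == "train_val"])
    test_idx = np.array([i for i, lid in enumerate(dataset.lesion_ids)
                         if split[lid] == "test"])
    normalizer = ClinicalNormalizer().fit(dataset.clinical.iloc[train_idx])
    (out / "normalizer.json").write_text(normalizer.to_json())
    model = ResponseNet(config.architecture, seed=config.seed)
    train_model(model, dataset.vois[train_idx],
                normalizer.transform_table(dataset.clinical.iloc[train_idx]),
                dataset.labels[train_idx], config.training, seed=config.seed)
    save_checkpoint(model, out / "model.npz")

    sal_dir = out / "saliency"
    sal_dir.mkdir(exist_ok=True)
    for i in test_idx[: config.n_saliency_examples]:
        lid = dataset.lesion_ids[i]
        cl = normalizer.transform_table(dataset.clinical.iloc[[i]])
        target = "C1" if dataset.labels[i] == 1 else "C2"
        smap = grad_cam(model, dataset.vois[i], cl, target)
        save_map_nifti(smap, sal_dir / f"{lid}_saliency.nii.gz")
        mid = dataset.vois[i].shape[0] // 2
        save_overlay(overlay(dataset.vois[i], smap, mid), sal_dir / f"{lid}_slice{mid}.png")

    manifest = {
        "package": "recistnet",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_lesions": len(cohort),
        "class_counts": cohort.class_counts(),
        "metrics_mean": report.mean,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
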