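"""Synthetic CT-lesion cohort generator.

Produces CT-like volumes with an injected ellipsoidal lesion phantom whose
intensity statistics differ by class, plus a class-correlated 15-element
clinical record per patient, so the full pipeline (VOI extraction, fusion
network, training, saliency) is testable without clinical data.

Simulation model: additive Gaussian background noise around a constant
background level; lesion voxels take ``lesion_mean * (1 + texture)`` with
a zero-mean Gaussian multiplicative texture field of SD
``texture_contrast``.  Voxel spacing is fixed at 2.5 mm slice thickness and
1 mm in-plane so millimetre thresholds (the 20 mm target-lesion rule) are
well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocessing import (
    CATEGORICAL_CODES,
    CLINICAL_FEATURES,
    CONTINUOUS_FEATURES,
    ROISelection,
)

VOXEL_SPACING_MM = (2.5, 1.0, 1.0)  # (z, y, x)
DEFAULT_VOLUME_SHAPE = (24, 80, 80)

#: Marginal distributions of the raw continuous clinical features:
#: ("lognormal", mu, sigma) draws exp(N(mu, sigma)); ("normal", mu, sigma)
#: draws N(mu, sigma).  Class effects shift the *underlying* normal by
#: ``effect_size * sigma`` (symmetric: -d/2 for C1, +d/2 for C2).
CLINICAL_MARGINALS: dict[str, tuple[str, float, float]] = {
    "wbc": ("lognormal", math.log(7.0), 0.35),
    "neutrophils": ("lognormal", math.log(4.5), 0.40),
    "lymphocytes": ("lognormal", math.log(1.8), 0.35),
    "eosinophils": ("lognormal", math.log(0.15), 0.50),
    "platelets": ("lognormal", math.log(250.0), 0.25),
    "albumin": ("normal", 40.0, 4.0),
    "ldh": ("lognormal", math.log(220.0), 0.30),
    "d_dimer": ("lognormal", math.log(0.6), 0.60),
    "urine_ph": ("normal", 6.0, 0.7),
    "proteins": ("normal", 70.0, 6.0),
    "bmi": ("normal", 26.0, 4.0),
    "age": ("normal", 66.0, 9.0),
}

#: Class-independent categorical frequencies (roughly matching the cohort
#: statistics the fixture emulates).
CATEGORICAL_PROBS = {
    "site": (0.09, 0.84, 0.07),
    "gender": (0.91, 0.09),
    "tobacco": (0.12, 0.37, 0.51),
}


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Parameters of one injected ellipsoidal lesion."""

    center_voxel: tuple[int, int, int]           # (z, y, x)
    axes_mm: tuple[float, float, float]          # ellipsoid semi-axes (z, y, x), mm
    class_label: str                             # "C1" or "C2"
    texture_contrast: float                      # SD of the multiplicative texture field
    visible_slices: int                          # lesion visible in this many leading slices
    noise_sd: float                              # background Gaussian noise SD
    lesion_mean: float = 120.0
    background_mean: float = 20.0

    def __post_init__(self):
        if any(a <= 0 for a in self.axes_mm):
            raise ValueError(f"axes_mm must all be positive, got {self.axes_mm}")
        if self.visible_slices < 1:
            raise ValueError(f"visible_slices must be >= 1, got {self.visible_slices}")
        if self.class_label not in ("C1", "C2"):
            raise ValueError(f"class_label must be C1 or C2, got {self.class_label!r}")

    @property
    def ld_mm(self) -> float:
        """Longest in-plane diameter implied by the ellipsoid semi-axes."""
        return 2.0 * max(self.axes_mm[1], self.axes_mm[2])


@dataclass
class GeneratedVolume:
    volume: np.ndarray             # rank-3 intensity array
    roi: ROISelection
    lesion_mask: np.ndarray        # bool, same shape as volume (visible part)
    valid_slices: int              # lesion-visible slices from the ROI anchor


def generate_volume(spec: SyntheticLesionSpec, seed: int,
                    volume_shape: tuple[int, int, int] = DEFAULT_VOLUME_SHAPE) -> GeneratedVolume:
    """Render one volume containing the lesion described by ``spec``.

    Deterministic given (spec, seed).  The ROI anchor is the first slice in
    which the lesion is visible and the box is the square in-plane bounding
    box (plus margin) taken at the slice of maximal lesion extension.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(volume_shape)
    cz, cy, cx = spec.center_voxel
    # voxel extent of each semi-axis; fail fast when the ellipsoid leaves the volume
    ext = [spec.axes_mm[i] / VOXEL_SPACING_MM[i] for i in range(3)]
    for axis, (c, e, s) in enumerate(zip((cz, cy, cx), ext, shape)):
        name = "zyx"[axis]
        if c - e < 0 or c + e > s - 1:
            raise ValueError(
                f"lesion extends outside the volume along axis {name!r} "
                f"(center {c}, extent {e:.1f} voxels, size {s})")

    volume = spec.background_mean + spec.noise_sd * rng.standard_normal(shape)
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    mask = (
        ((zz - cz) * VOXEL_SPACING_MM[0] / spec.axes_mm[0]) ** 2
        + ((yy - cy) * VOXEL_SPACING_MM[1] / spec.axes_mm[1]) ** 2
        + ((xx - cx) * VOXEL_SPACING_MM[2] / spec.axes_mm[2]) ** 2
    ) <= 1.0

    z_any = np.flatnonzero(mask.any(axis=(1, 2)))
    z_first = int(z_any[0])
    # clip visibility: lesion absent beyond `visible_slices` slices
    visible = mask.copy()
    visible[z_first + spec.visible_slices:] = False

    texture = 1.0 + spec.texture_contrast * rng.standard_normal(int(visible.sum()))
    volume[visible] = spec.lesion_mean * texture

    # box from the maximal-extension slice, made square with a small margin
    areas = visible.sum(axis=(1, 2))
    z_max = int(np.argmax(areas))
    ys, xs = np.nonzero(visible[z_max])
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    side = max(y1 - y0, x1 - x0) + 4
    yc, xc = (y0 + y1) // 2, (x0 + x1) // 2
    half = side // 2
    y0 = max(0, yc - half); y1 = min(shape[1], yc - half + side)
    x0 = max(0, xc - half); x1 = min(shape[2], xc - half + side)
    roi = ROISelection(anchor_slice=z_first, x0=x0, y0=y0, x1=x1, y1=y1)
    valid = int(visible.any(axis=(1, 2)).sum())
    return GeneratedVolume(volume=volume.astype(np.float64), roi=roi,
                           lesion_mask=visible, valid_slices=valid)


# ---------------------------------------------------------------------------
# Clinical vectors
# ---------------------------------------------------------------------------

def generate_clinical(class_label: str, seed: int,
                      effects: dict[str, float] | None = None) -> dict:
    """Draw one raw (unnormalized) 15-field clinical record.

    ``effects`` maps continuous feature name -> effect size d (in SDs of
    the feature's underlying normal): class C1 is shifted by -d/2, C2 by
    +d/2, so the between-class mean difference is d SDs.  With all effects
    zero the two class distributions are identical (same seed gives the
    identical record for either class).
    """
    if class_label not in ("C1", "C2"):
        raise ValueError(f"class_label must be C1 or C2, got {class_label!r}")
    effects = effects or {}
    unknown = set(effects) - set(CONTINUOUS_FEATURES)
    if unknown:
        raise ValueError(f"effects refer to unknown/categorical features: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    sign = -0.5 if class_label == "C1" else 0.5
    record: dict = {}
    for f in CLINICAL_FEATURES:
        if f in CATEGORICAL_CODES:
            labels = CATEGORICAL_CODES[f]
            record[f] = labels[rng.choice(len(labels), p=CATEGORICAL_PROBS[f])]
        else:
            kind, mu, sigma = CLINICAL_MARGINALS[f]
            z = rng.standard_normal() + sign * effects.get(f, 0.0)
            latent = mu + sigma * z
            record[f] = float(np.exp(latent)) if kind == "lognormal" else float(latent)
    return record


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassImagingParams:
    """Per-class lesion rendering knobs."""

    lesion_mean: float
    texture_contrast: float
    axes_mm: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (6.0, 10.0), (11.0, 16.0), (11.0, 16.0))  # (z, y, x) semi-axis ranges, mm
    visible_slices: tuple[int, int] = (5, 16)


@dataclass(frozen=True)
class CohortConfig:
    n_class1: int = 43
    n_class2: int = 63
    lesions_per_patient: tuple[int, int] = (2, 3)
    train_counts: tuple[int, int] = (28, 48)    # (C1, C2) lesions in train/val
    volume_shape: tuple[int, int, int] = DEFAULT_VOLUME_SHAPE
    noise_sd: float = 5.0
    background_mean: float = 20.0
    class1: ClassImagingParams = field(default_factory=lambda: ClassImagingParams(60.0, 0.05))
    class2: ClassImagingParams = field(default_factory=lambda: ClassImagingParams(180.0, 0.15))
    clinical_effects: dict[str, float] = field(default_factory=dict)

    @classmethod
    def easy(cls, **kw) -> "CohortConfig":
        """Strong imaging class signal (the generator's separability knob).

        Lesions are bright blobs on a near-zero background at class-specific
        intensity levels, spanning the full VOI depth.  With a fixed
        intensity window the class evidence is then confined to (and
        positively detectable inside) the lesion for both classes, which is
        what the saliency-localization acceptance property measures.
        """
        kw.setdefault("background_mean", 5.0)
        kw.setdefault("noise_sd", 3.0)
        kw.setdefault("class1", ClassImagingParams(
            90.0, 0.10, axes_mm=((20.0, 24.0), (11.0, 16.0), (11.0, 16.0)),
            visible_slices=(16, 16)))
        kw.setdefault("class2", ClassImagingParams(
            220.0, 0.10, axes_mm=((20.0, 24.0), (11.0, 16.0), (11.0, 16.0)),
            visible_slices=(16, 16)))
        return cls(**kw)

    @classmethod
    def null(cls, **kw) -> "CohortConfig":
        """No class signal anywhere (both classes share all parameters)."""
        shared = ClassImagingParams(120.0, 0.10)
        return cls(class1=shared, class2=shared, clinical_effects={}, **kw)

    @classmethod
    def clinical_only(cls, effects: dict[str, float] | None = None, **kw) -> "CohortConfig":
        """Class signal confined to the clinical features."""
        shared = ClassImagingParams(120.0, 0.10)
        effects = effects if effects is not None else {
            "ldh": 4.0, "albumin": 4.0, "wbc": 3.0, "d_dimer": 3.0}
        return cls(class1=shared, class2=shared, clinical_effects=effects, **kw)


@dataclass
class LesionRecord:
    patient_id: str
    lesion_id: str
    class_label: str
    roi: ROISelection
    valid_slices: int
    clinical: dict
    split: str  # "train_val" or "test"


@dataclass
class SyntheticCohort:
    """Cohort table plus (in-memory) volumes and lesion masks."""

    records: list[LesionRecord]
    volumes: dict[str, np.ndarray]
    lesion_masks: dict[str, np.ndarray]
    config: CohortConfig
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    @property
    def split(self) -> dict[str, str]:
        return {r.lesion_id: r.split for r in self.records}

    def class_counts(self) -> dict[str, int]:
        out = {"C1": 0, "C2": 0}
        for r in self.records:
            out[r.class_label] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "lesion_id": r.lesion_id,
                "class": r.class_label,
                "volume": f"{r.lesion_id}.nii.gz",
                "roi_json": r.roi.to_json(),
                "valid_slices": r.valid_slices,
                "split": r.split,
            }
            row.update({f: r.clinical[f] for f in CLINICAL_FEATURES})
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        """Write volumes as NIfTI plus the cohort CSV."""
        import pathlib

        import nibabel as nib

        out = pathlib.Path(out_dir)
        (out / "volumes").mkdir(parents=True, exist_ok=True)
        affine = np.diag([VOXEL_SPACING_MM[2], VOXEL_SPACING_MM[1], VOXEL_SPACING_MM[0], 1.0])
        for lid, vol in self.volumes.items():
            # NIfTI stores x fastest: transpose (z,y,x) -> (x,y,z)
            img = nib.Nifti1Image(np.ascontiguousarray(vol.T).astype(np.float32), affine)
            nib.save(img, str(out / "volumes" / f"{lid}.nii.gz"))
        self.to_dataframe().to_csv(out / "cohort.csv", index=False)

    @classmethod
    def load(cls, in_dir) -> "SyntheticCohort":
        """Read back a cohort written by :meth:`save` (masks are not stored)."""
        import pathlib

        import nibabel as nib

        root = pathlib.Path(in_dir)
        df = pd.read_csv(root / "cohort.csv")
        records, volumes = [], {}
        for _, row in df.iterrows():
            records.append(LesionRecord(
                patient_id=str(row["patient_id"]),
                lesion_id=str(row["lesion_id"]),
                class_label=str(row["class"]),
                roi=ROISelection.from_json(row["roi_json"]),
                valid_slices=int(row["valid_slices"]),
                clinical={f: row[f] for f in CLINICAL_FEATURES},
                split=str(row["split"]),
            ))
            img = nib.load(root / "volumes" / str(row["volume"]))
            volumes[str(row["lesion_id"])] = np.asarray(img.get_fdata()).T
        return cls(records=records, volumes=volumes, lesion_masks={},
                   config=None, seed=-1)


def _draw_patient_sizes(total: int, size_range: tuple[int, int], rng: np.random.Generator) -> list[int]:
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad lesions_per_patient range {size_range}")
    sizes, left = [], total
    while left > 0:
        s = min(int(rng.integers(lo, hi + 1)), left)
        sizes.append(s)
        left -= s
    return sizes


def _choose_train_patients(sizes: list[int], target: int, rng: np.random.Generator) -> list[int]:
    """Pick a patient subset whose lesion counts sum exactly to ``target``
    (subset-sum DP over a shuffled order); raises if infeasible."""
    order = list(rng.permutation(len(sizes)))
    reachable = {0: None}  # sum -> (prev_sum, patient_index)
    for idx in order:
        s = sizes[idx]
        updates = {}
        for tot, _ in reachable.items():
            nt = tot + s
            if nt <= target and nt not in reachable:
                updates[nt] = (tot, idx)
        reachable.update(updates)
        if target in reachable:
            break
    if target not in reachable:
        raise ValueError(
            f"requested train/val lesion count {target} is infeasible under "
            f"patient-disjointness with patient sizes {sizes}")
    chosen, tot = [], target
    while tot != 0:
        prev, idx = reachable[tot]
        chosen.append(idx)
        tot = prev
    return chosen


def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    n_class1: int | None = None, n_class2: int | None = None) -> SyntheticCohort:
    """Generate a full cohort with exact class counts and a patient-disjoint
    train_val/test split matching ``config.train_counts``."""
    config = config or CohortConfig()
    if n_class1 is not None or n_class2 is not None:
        config = replace(config, n_class1=n_class1 or config.n_class1,
                         n_class2=n_class2 or config.n_class2)
    if config.n_class1 < 1 or config.n_class2 < 1:
        raise ValueError("per-class lesion counts must be positive")
    if not (0 <= config.train_counts[0] <= config.n_class1
            and 0 <= config.train_counts[1] <= config.n_class2):
        raise ValueError("train_counts exceed cohort composition")
    rng = np.random.default_rng(seed)
    shape = config.volume_shape

    records: list[LesionRecord] = []
    volumes: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    patient_counter = 0
    for cls, n_lesions, params, train_target in (
        ("C1", config.n_class1, config.class1, config.train_counts[0]),
        ("C2", config.n_class2, config.class2, config.train_counts[1]),
    ):
        sizes = _draw_patient_sizes(n_lesions, config.lesions_per_patient, rng)
        train_patients = set(_choose_train_patients(sizes, train_target, rng))
        lesion_counter = 0
        for p_idx, size in enumerate(sizes):
            patient_counter += 1
            pid = f"P{patient_counter:03d}"
            split = "train_val" if p_idx in train_patients else "test"
            clinical = generate_clinical(cls, seed=int(rng.integers(2 ** 31)),
                                         effects=config.clinical_effects)
            for _ in range(size):
                lesion_counter += 1
                lid = f"{pid}_L{lesion_counter:03d}"
                axes = tuple(float(rng.uniform(lo, hi)) for lo, hi in params.axes_mm)
                ext = [axes[i] / VOXEL_SPACING_MM[i] for i in range(3)]
                center = tuple(
                    int(rng.integers(int(np.ceil(ext[i])) + 1, shape[i] - int(np.ceil(ext[i])) - 1))
                    for i in range(3)
                )
                vis = int(rng.integers(params.visible_slices[0], params.visible_slices[1] + 1))
                spec = SyntheticLesionSpec(
                    center_voxel=center, axes_mm=axes, class_label=cls,
                    texture_contrast=params.texture_contrast, visible_slices=vis,
                    noise_sd=config.noise_sd, lesion_mean=params.lesion_mean,
                    background_mean=config.background_mean,
                )
                gen = generate_volume(spec, seed=int(rng.integers(2 ** 31)), volume_shape=shape)
                records.append(LesionRecord(
                    patient_id=pid, lesion_id=lid, class_label=cls, roi=gen.roi,
                    valid_slices=gen.valid_slices, clinical=clinical, split=split))
                volumes[lid] = gen.volume
                masks[lid] = gen.lesion_mask

    cohort = SyntheticCohort(records=records, volumes=volumes, lesion_masks=masks,
                             config=config, seed=seed)
    counts = cohort.class_counts()
    assert counts["C1"] == config.n_class1 and counts["C2"] == config.n_class2
    return cohort
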