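"""VOI extraction and clinical-vector encoding.

A lesion annotation is a 2D box drawn on the slice of maximal lesion
extension; the box is propagated over 16 consecutive slices, each crop is
bi-cubically resized to 64x64, and slices where the lesion is not visible
are zeroed, producing the fixed 16x64x64 network input.

The 15 clinical/hemato-chemical features are encoded as: categorical
fields (site, gender, tobacco) mapped to small integer codes, continuous
fields z-scored with statistics fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

VOI_SLICES = 16
VOI_SIZE = (64, 64)

#: Fixed feature order of the 15-element clinical vector.
CLINICAL_FEATURES = (
    "site",
    "wbc",
    "neutrophils",
    "lymphocytes",
    "eosinophils",
    "platelets",
    "albumin",
    "ldh",
    "d_dimer",
    "urine_ph",
    "proteins",
    "bmi",
    "age",
    "gender",
    "tobacco",
)

#: Categorical label -> integer code tables (order defines the code).
CATEGORICAL_CODES = {
    "site": ("upper", "lower", "both"),
    "gender": ("male", "female"),
    "tobacco": ("never", "current", "former"),
}

CONTINUOUS_FEATURES = tuple(f for f in CLINICAL_FEATURES if f not in CATEGORICAL_CODES)


def encode_categorical(feature: str, label: str) -> int:
    labels = CATEGORICAL_CODES[feature]
    try:
        return labels.index(str(label))
    except ValueError:
        raise ValueError(f"unknown {feature} label {label!r}; expected one of {labels}") from None


def decode_categorical(feature: str, code: int) -> str:
    labels = CATEGORICAL_CODES[feature]
    if not 0 <= int(code) < len(labels):
        raise ValueError(f"invalid {feature} code {code}")
    return labels[int(code)]


# ---------------------------------------------------------------------------
# ROI / VOI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISelection:
    """2D lesion box on its anchor slice: half-open, 0-based coordinates.

    ``x`` indexes columns (last array axis), ``y`` rows.
    """

    anchor_slice: int
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate box ({self.x0},{self.y0},{self.x1},{self.y1})")

    @property
    def box(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    def to_json(self) -> str:
        return json.dumps({"slice": self.anchor_slice, "x0": self.x0, "y0": self.y0,
                           "x1": self.x1, "y1": self.y1})

    @classmethod
    def from_json(cls, s: str) -> "ROISelection":
        d = json.loads(s)
        return cls(anchor_slice=int(d["slice"]), x0=int(d["x0"]), y0=int(d["y0"]),
                   x1=int(d["x1"]), y1=int(d["y1"]))


@dataclass
class VOI:
    """16x64x64 intensity block; slices >= valid_slices are all-zero."""

    intensities: np.ndarray
    valid_slices: int

    def __post_init__(self):
        if self.intensities.shape != (VOI_SLICES, *VOI_SIZE):
            raise ValueError(f"VOI must be {(VOI_SLICES, *VOI_SIZE)}, got {self.intensities.shape}")
        if not 1 <= self.valid_slices <= VOI_SLICES:
            raise ValueError(f"valid_slices must be in [1,{VOI_SLICES}], got {self.valid_slices}")


def resize_bicubic(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bi-cubic resize with corner-aligned sampling (exact at grid corners)."""
    in_h, in_w = img.shape
    if (in_h, in_w) == tuple(out_shape):
        return img.astype(np.float64)
    rows = np.linspace(0.0, in_h - 1.0, out_shape[0])
    cols = np.linspace(0.0, in_w - 1.0, out_shape[1])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(img.astype(np.float64), [rr, cc], order=3, mode="mirror")


def extract_voi(volume: np.ndarray, roi: ROISelection, valid_slices: int | None = None,
                mode: str = "anchor_start") -> VOI:
    """Crop the ROI box over 16 consecutive slices and resize each to 64x64.

    ``mode`` selects whether the 16 slices start at the anchor slice
    (default) or are centred on it.  ``valid_slices`` is the annotated
    number of leading slices where the lesion is visible; later slices are
    zeroed.  Slices falling outside the volume are likewise zero.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"volume must be rank-3, got shape {volume.shape}")
    nz, ny, nx = volume.shape
    if not 0 <= roi.anchor_slice < nz:
        raise ValueError(f"anchor slice {roi.anchor_slice} outside volume with {nz} slices")
    if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > nx or roi.y1 > ny:
        raise ValueError(f"ROI box {roi.box} outside volume in-plane bounds ({ny},{nx})")
    if mode == "anchor_start":
        z0 = roi.anchor_slice
    elif mode == "centered":
        z0 = max(0, roi.anchor_slice - VOI_SLICES // 2)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    available = min(VOI_SLICES, nz - z0)
    if available < 1:
        raise ValueError("no slices available for VOI extraction")
    valid = VOI_SLICES if valid_slices is None else int(valid_slices)
    valid = max(1, min(valid, available))

    out = np.zeros((VOI_SLICES, *VOI_SIZE), dtype=np.float64)
    for i in range(valid):
        crop = volume[z0 + i, roi.y0:roi.y1, roi.x0:roi.x1]
        out[i] = resize_bicubic(crop, VOI_SIZE)
    return VOI(intensities=out, valid_slices=valid)


def normalize_voi(voi: VOI) -> VOI:
    """Per-VOI min-max scaling to [0, 1] (flat input maps to zeros)."""
    x = voi.intensities
    lo, hi = float(x.min()), float(x.max())
    scaled = np.zeros_like(x) if hi <= lo else (x - lo) / (hi - lo)
    return VOI(intensities=scaled, valid_slices=voi.valid_slices)


# ---------------------------------------------------------------------------
# Clinical encoding
# ---------------------------------------------------------------------------

@dataclass
class ClinicalVector:
    values: np.ndarray
    feature_names: tuple[str, ...] = CLINICAL_FEATURES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.feature_names),):
            raise ValueError(f"expected {len(self.feature_names)} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clinical vector contains non-finite values")


class ClinicalNormalizer:
    """Z-scoring statistics for the continuous features, fitted on the
    training split only; categorical features pass through as codes."""

    def __init__(self, means: dict[str, float] | None = None, stds: dict[str, float] | None = None):
        self.means = dict(means or {})
        self.stds = dict(stds or {})

    @property
    def fitted(self) -> bool:
        return bool(self.means)

    def fit(self, rows: pd.DataFrame) -> "ClinicalNormalizer":
        missing = [f for f in CLINICAL_FEATURES if f not in rows.columns]
        if missing:
            raise ValueError(f"clinical table missing fields: {missing}")
        for f in CONTINUOUS_FEATURES:
            vals = rows[f].astype(float).to_numpy()
            self.means[f] = float(vals.mean())
            sd = float(vals.std(ddof=0))
            self.stds[f] = sd if sd > 1e-12 else 1.0
        return self

    def transform(self, record) -> ClinicalVector:
        return encode_clinical(record, self)

    def transform_table(self, rows: pd.DataFrame) -> np.ndarray:
        return np.stack([self.transform(row).values for _, row in rows.iterrows()])

    def to_json(self) -> str:
        return json.dumps({"means": self.means, "stds": self.stds})

    @classmethod
    def from_json(cls, s: str) -> "ClinicalNormalizer":
        d = json.loads(s)
        return cls(means=d["means"], stds=d["stds"])


def encode_clinical(record, normalizer: ClinicalNormalizer) -> ClinicalVector:
    """Encode one raw clinical record into the normalized 15-vector.

    ``record`` is any mapping (dict, pandas row) with the 15 fields of
    :data:`CLINICAL_FEATURES`.  Raises ``KeyError`` naming the first
    missing field.
    """
    if not normalizer.fitted:
        raise ValueError("normalizer must be fitted on the training split first")
    values = []
    for f in CLINICAL_FEATURES:
        try:
            raw = record[f]
        except (KeyError, IndexError):
            raise KeyError(f"missing clinical field: {f!r}") from None
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            raise KeyError(f"missing clinical field: {f!r}")
        if f in CATEGORICAL_CODES:
            values.append(float(raw) if not isinstance(raw, str) else float(encode_categorical(f, raw)))
        else:
            values.append((float(raw) - normalizer.means[f]) / normalizer.stds[f])
    return ClinicalVector(np.array(values))
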