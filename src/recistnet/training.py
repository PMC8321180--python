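"""Loss, augmentation, patient-disjoint cross-validation, and metrics.

Protocol defaults follow the reference setup: Adam with initial learning
rate 0.01, mini-batch size 4, negative log-likelihood loss with L2
regularization (lambda = 1e-4), random in-plane rotation/translation
augmentation, and k = 5 patient-disjoint stratified folds.  Metric
conventions: positive = C1 (responder).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .network import ArchitectureSpec, ResponseNet
from .nn import Adam
from .preprocessing import VOI, ClinicalNormalizer, extract_voi, normalize_voi
from .synthetic_cohort import SyntheticCohort

EPS_PROB = 1e-12


@dataclass
class TrainingConfig:
    learning_rate: float = 0.01
    batch_size: int = 4
    l2_lambda: float = 1e-4
    epochs: int = 50
    seed: int = 0
    k: int = 5
    augment: bool = True
    max_rotation_deg: float = 180.0
    max_translation: int = 2
    downsample: tuple[int, int, int] = (1, 1, 1)  # VOI average-pooling factors

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["downsample"] = list(d["downsample"])
        return d


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def nll_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Sum-reduced negative log-likelihood of binary labels.

    ``probabilities`` is either (N, 2) class probabilities (column 1 =
    P(C1)) or the 1D vector of P(C1).  ``labels`` are 0/1 with 1 = C1.
    Probabilities are clamped to [1e-12, 1 - 1e-12] before the logs.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim == 2:
        p = p[:, 1]
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    p = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def l2_penalty(model, lam: float) -> float:
    """lambda * sum of squared parameter values (all learnable tensors)."""
    return float(lam * sum(np.sum(p.value ** 2) for p in model.parameters()))


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def apply_transform(voi: np.ndarray, angle_deg: float, shift: tuple[int, int]) -> np.ndarray:
    """In-plane rotation (bilinear) + integer translation, applied identically
    to every slice; output shape unchanged, exposed regions zero-filled."""
    out = np.asarray(voi, dtype=np.float64)
    if angle_deg != 0.0:
        out = ndimage.rotate(out, angle_deg, axes=(1, 2), reshape=False,
                             order=1, mode="constant", cval=0.0)
    dy, dx = int(shift[0]), int(shift[1])
    if dy or dx:
        shifted = np.zeros_like(out)
        ys = slice(max(dy, 0), out.shape[1] + min(dy, 0))
        xs = slice(max(dx, 0), out.shape[2] + min(dx, 0))
        ys_src = slice(max(-dy, 0), out.shape[1] + min(-dy, 0))
        xs_src = slice(max(-dx, 0), out.shape[2] + min(-dx, 0))
        shifted[:, ys, xs] = out[:, ys_src, xs_src]
        out = shifted
    return out


def augment(voi: np.ndarray, seed_or_rng, max_rotation_deg: float = 180.0,
            max_translation: int = 2) -> np.ndarray:
    """Draw a random rotation/translation from the seed and apply it."""
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    angle = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
    shift = tuple(int(v) for v in rng.integers(-max_translation, max_translation + 1, size=2))
    return apply_transform(voi, angle, shift)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class LesionDataset:
    """In-memory training arrays; clinical rows stay raw (normalization is
    fitted per training split inside cross-validation)."""

    vois: np.ndarray               # (N, D, H, W), min-max normalized
    clinical: pd.DataFrame         # raw rows, one per lesion
    labels: np.ndarray             # (N,), 1 = C1 responder
    patient_ids: list[str]
    lesion_ids: list[str]
    lesion_masks: np.ndarray | None = None  # (N, D, H, W) bool, VOI-aligned

    def __len__(self) -> int:
        return len(self.labels)


def _downsample(voi: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    if tuple(factors) == (1, 1, 1):
        return voi
    d, h, w = voi.shape
    fd, fh, fw = factors
    if d % fd or h % fh or w % fw:
        raise ValueError(f"downsample factors {factors} do not divide VOI shape {voi.shape}")
    return voi.reshape(d // fd, fd, h // fh, fh, w // fw, fw).mean(axis=(1, 3, 5))


def dataset_from_cohort(cohort: SyntheticCohort, downsample: tuple[int, int, int] = (1, 1, 1),
                        with_masks: bool = False, normalization: str = "minmax",
                        intensity_window: tuple[float, float] = (0.0, 255.0)) -> LesionDataset:
    """Extract normalized (optionally average-pooled) VOIs for every lesion.

    ``normalization`` is "minmax" (per-VOI min-max to [0, 1]) or "window"
    (fixed intensity window, clipped) — the latter keeps absolute intensity
    information local to the lesion instead of leaking it into the
    rescaled background.
    """
    if normalization not in ("minmax", "window"):
        raise ValueError(f"unknown normalization {normalization!r}")
    lo, hi = intensity_window
    vois, rows, labels, pids, lids, mask_list = [], [], [], [], [], []
    for rec in cohort.records:
        vol = cohort.volumes[rec.lesion_id]
        voi = extract_voi(vol, rec.roi, valid_slices=rec.valid_slices)
        if normalization == "minmax":
            voi = normalize_voi(voi)
        else:
            scaled = np.clip((voi.intensities - lo) / (hi - lo), 0.0, 1.0)
            scaled[voi.valid_slices:] = 0.0
            voi = VOI(intensities=scaled, valid_slices=voi.valid_slices)
        vois.append(_downsample(voi.intensities, downsample))
        rows.append(rec.clinical)
        labels.append(1 if rec.class_label == "C1" else 0)
        pids.append(rec.patient_id)
        lids.append(rec.lesion_id)
        if with_masks:
            mask_voi = extract_voi(cohort.lesion_masks[rec.lesion_id].astype(np.float64),
                                   rec.roi, valid_slices=rec.valid_slices)
            mask_list.append(_downsample(mask_voi.intensities, downsample) > 0.5)
    return LesionDataset(
        vois=np.stack(vois),
        clinical=pd.DataFrame(rows),
        labels=np.asarray(labels, dtype=np.int64),
        patient_ids=pids,
        lesion_ids=lids,
        lesion_masks=np.stack(mask_list) if with_masks else None,
    )


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def kfold_split(patient_ids: list[str], labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Patient-disjoint, class-stratified fold assignment per lesion.

    Patients (each carrying one class) are shuffled and greedily assigned,
    largest first, to the fold currently holding the fewest lesions of that
    class, which keeps per-fold class proportions close to global.
    """
    patient_ids = list(patient_ids)
    labels = np.asarray(labels)
    patients: dict[str, dict] = {}
    for pid, y in zip(patient_ids, labels):
        info = patients.setdefault(pid, {"n": 0, "label": int(y)})
        info["n"] += 1
        if info["label"] != int(y):
            raise ValueError(f"patient {pid} has lesions of both classes")
    if k > len(patients):
        raise ValueError(f"k={k} exceeds number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    fold_of_patient: dict[str, int] = {}
    for cls in (0, 1):
        plist = [p for p, info in patients.items() if info["label"] == cls]
        rng.shuffle(plist)
        plist.sort(key=lambda p: -patients[p]["n"])
        load = [0] * k
        for p in plist:
            f = int(np.argmin(load))
            fold_of_patient[p] = f
            load[f] += patients[p]["n"]
    n_patient_folds = len(set(fold_of_patient.values()))
    if n_patient_folds < k:
        raise ValueError(
            f"stratification infeasible: only {n_patient_folds} non-empty folds for k={k}; "
            f"per-class patient counts: "
            f"{ {c: sum(1 for i in patients.values() if i['label'] == c) for c in (0, 1)} }")
    return np.array([fold_of_patient[p] for p in patient_ids], dtype=np.int64)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(predictions: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Counts with positive = C1 (label 1)."""
    p = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    return ConfusionCounts(
        tp=int(((p == 1) & (y == 1)).sum()),
        tn=int(((p == 0) & (y == 0)).sum()),
        fp=int(((p == 1) & (y == 0)).sum()),
        fn=int(((p == 0) & (y == 1)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", RuntimeWarning)
        return math.nan
    return num / den


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy"),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
        "f1": _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, "f1"),
    }


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> tuple[ConfusionCounts, dict[str, float]]:
    c = confusion(predictions, labels)
    return c, metrics_from_confusion(c)


@dataclass
class MetricsReport:
    mean: dict[str, float]
    sd: dict[str, float]
    per_fold: list[dict] = field(default_factory=list)

    def summary_table(self) -> pd.DataFrame:
        cols = ["accuracy", "sensitivity", "specificity", "f1"]
        return pd.DataFrame(
            [{m: f"{self.mean[m]:.3f} ± {self.sd[m]:.3f}" for m in cols}])

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "per_fold": self.per_fold}


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train_model(model: ResponseNet, vois: np.ndarray, clinical: np.ndarray | None,
                labels: np.ndarray, config: TrainingConfig, seed: int) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch summed NLL losses.

    Raises ``RuntimeError`` on a non-finite loss (diverged fold).
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.l2_lambda)
    n = len(labels)
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), labels] = 1.0
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = vois[idx]
            if config.augment:
                xb = np.stack([
                    augment(v, rng, config.max_rotation_deg, config.max_translation)
                    for v in xb])
            cb = None if clinical is None else clinical[idx]
            probs, fw = model.forward(xb, cb, train=True)
            loss = nll_loss(probs, labels[idx])
            if not math.isfinite(loss) or not np.all(np.isfinite(fw["logits"])):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {start}")
            opt.zero_grad()
            model.backward(probs - onehot[idx])  # d(sum NLL)/d(logits)
            opt.step()
            total += loss
        history.append(total)
    return history


def cross_validate(dataset: LesionDataset, spec: ArchitectureSpec,
                   config: TrainingConfig, use_clinical: bool = True) -> MetricsReport:
    """Patient-disjoint stratified k-fold CV; one freshly seeded model per
    fold; metrics aggregated as mean +- SD over folds."""
    folds = kfold_split(dataset.patient_ids, dataset.labels, config.k, config.seed)
    per_fold = []
    for f in range(config.k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        normalizer = ClinicalNormalizer().fit(dataset.clinical.iloc[train_idx])
        cl_train = cl_test = None
        if use_clinical and spec.clinical_dim:
            cl_train = normalizer.transform_table(dataset.clinical.iloc[train_idx])
            cl_test = normalizer.transform_table(dataset.clinical.iloc[test_idx])
        model = ResponseNet(spec, seed=config.seed * 1000 + f)
        train_model(model, dataset.vois[train_idx], cl_train,
                    dataset.labels[train_idx], config, seed=config.seed * 1000 + f)
        probs = model.predict_proba(dataset.vois[test_idx], cl_test)
        preds = probs.argmax(axis=1)
        counts, m = evaluate(preds, dataset.labels[test_idx])
        per_fold.append({"fold": f, "n_test": int(len(test_idx)),
                         "confusion": asdict(counts), **m})
    names = ["accuracy", "sensitivity", "specificity", "f1"]
    arr = {m: np.array([pf[m] for pf in per_fold], dtype=np.float64) for m in names}
    return MetricsReport(
        mean={m: float(arr[m].mean()) for m in names},
        sd={m: float(arr[m].std(ddof=0)) for m in names},
        per_fold=per_fold,
    )
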