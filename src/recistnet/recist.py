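"""RECIST 1.1 target-lesion selection and response categorisation.

Implements the four rules used for binary outcome labelling:

* target lesions are those with longest diameter (LD) >= 20 mm;
* the baseline is the sum of target-lesion LDs;
* CR  — every follow-up target LD is 0 (lesions disappeared);
* PD  — follow-up LD sum increased by at least 20% of baseline;
* PR  — follow-up LD sum decreased by at least 30% of baseline;
* SD  — otherwise.

CR/PR/SD map to binary class C1 (responder), PD to C2.  Precedence is
CR > PD > PR > SD so the function is total over nonnegative inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

TARGET_LD_MM = 20.0
PR_THRESHOLD = 0.7   # follow-up sum <= 70% of baseline
PD_THRESHOLD = 1.2   # follow-up sum >= 120% of baseline


class ResponseCategory(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    PD = "PD"
    SD = "SD"


class BinaryClass(str, enum.Enum):
    C1 = "C1"  # responder: CR / PR / SD
    C2 = "C2"  # progressive disease


@dataclass(frozen=True)
class LesionMeasurement:
    lesion_id: str
    longest_diameter_mm: float

    def __post_init__(self):
        if self.longest_diameter_mm < 0:
            raise ValueError(f"lesion {self.lesion_id}: negative LD {self.longest_diameter_mm}")


def select_target_lesions(lesions: Iterable[LesionMeasurement]) -> list[LesionMeasurement]:
    """Keep lesions with LD >= 20 mm (inclusive), preserving order."""
    return [m for m in lesions if m.longest_diameter_mm >= TARGET_LD_MM]


def baseline_ld_sum(targets: Sequence[LesionMeasurement]) -> float:
    if not targets:
        raise ValueError("baseline requires at least one target lesion")
    return float(sum(m.longest_diameter_mm for m in targets))


def classify_response(baseline_sum: float, followup_lds: Sequence[float]) -> ResponseCategory:
    """Categorise a follow-up assessment against a baseline LD sum."""
    if baseline_sum <= 0:
        raise ValueError(f"baseline LD sum must be positive, got {baseline_sum}")
    lds = [float(v) for v in followup_lds]
    if any(v < 0 for v in lds):
        raise ValueError("negative follow-up LD")
    if lds and all(v == 0.0 for v in lds):
        return ResponseCategory.CR
    total = sum(lds)
    if total >= PD_THRESHOLD * baseline_sum:
        return ResponseCategory.PD
    if total <= PR_THRESHOLD * baseline_sum:
        return ResponseCategory.PR
    return ResponseCategory.SD


def to_binary_class(category: ResponseCategory) -> BinaryClass:
    return BinaryClass.C2 if category is ResponseCategory.PD else BinaryClass.C1


# ---------------------------------------------------------------------------
# Longitudinal measurement tables (lesion_id, timepoint, LD_mm)
# ---------------------------------------------------------------------------

def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"lesion_id", "timepoint", "LD_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return df


def assess_table(df: pd.DataFrame) -> pd.DataFrame:
    """Assess each follow-up timepoint of a longitudinal table.

    Baseline is the earliest timepoint; target lesions are selected there
    and tracked by id.  Returns one row per later timepoint with the
    category and binary class.
    """
    timepoints = sorted(df["timepoint"].unique())
    if len(timepoints) < 2:
        raise ValueError("need a baseline and at least one follow-up timepoint")
    t0 = timepoints[0]
    base = df[df["timepoint"] == t0]
    targets = select_target_lesions(
        LesionMeasurement(str(r.lesion_id), float(r.LD_mm)) for r in base.itertuples()
    )
    base_sum = baseline_ld_sum(targets)
    target_ids = [m.lesion_id for m in targets]
    rows = []
    for t in timepoints[1:]:
        fu = df[df["timepoint"] == t].set_index(df[df["timepoint"] == t]["lesion_id"].astype(str))
        lds = []
        for lid in target_ids:
            if lid not in fu.index:
                raise ValueError(f"timepoint {t}: missing measurement for target lesion {lid}")
            lds.append(float(fu.loc[lid, "LD_mm"]))
        cat = classify_response(base_sum, lds)
        rows.append({
            "timepoint": t,
            "baseline_ld_sum": base_sum,
            "followup_ld_sum": sum(lds),
            "category": cat.value,
            "binary_class": to_binary_class(cat).value,
        })
    return pd.DataFrame(rows)
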