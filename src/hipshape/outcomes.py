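"""Radiographic hip OA grading (Croft score) and pain outcome construction.

Radiographs are scored per joint for joint space narrowing (JSN;
medial, lateral, concentric; each 0-4), osteophytes at four sites
(lateral/inferior x acetabular/femoral; each 0-3), subchondral
sclerosis (0-3), bone cysts (0-3) and femoral head deformity (0-3).
The Croft grade aggregates these into a 0-5 ordinal scale:

    0  no features
    1  osteophytosis only
    2  JSN only
    3  two of {osteophytosis, JSN, sclerosis, cysts}
    4  three of those four
    5  grade-4 criteria plus femoral head deformity

"Presence" of a feature group means any of its sites/regions graded >= 1.
A sclerosis-only or cysts-only film matches none of grades 1-5 and is
graded 0 (the definition of radiographic OA requires osteophytes or
JSN); see the methods note for discussion of this corner case.

Radiographic hip OA (RHOA) is Croft grade >= 2 (moderate; the primary
definition) or >= 3 (severe; the sensitivity definition).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "RadiographReading",
    "PainOutcomes",
    "OSTEOPHYTE_SITES",
    "JSN_REGIONS",
    "croft_grade",
    "rhoa_case",
    "binary_feature",
    "prevalence",
    "bmi",
    "readings_to_frame",
    "frame_to_readings",
]

OSTEOPHYTE_SITES = (
    "osteophyte_lateral_acetabular",
    "osteophyte_lateral_femoral",
    "osteophyte_inferior_acetabular",
    "osteophyte_inferior_femoral",
)
JSN_REGIONS = ("jsn_medial", "jsn_lateral", "jsn_concentric")

_GRADE_RANGES = {
    **{s: (0, 3) for s in OSTEOPHYTE_SITES},
    **{r: (0, 4) for r in JSN_REGIONS},
    "cysts": (0, 3),
    "sclerosis": (0, 3),
    "head_deformity": (0, 3),
}


@dataclass(frozen=True)
class RadiographReading:
    """Component grades from one hip radiograph."""

    jsn_medial: int = 0
    jsn_lateral: int = 0
    jsn_concentric: int = 0
    osteophyte_lateral_acetabular: int = 0
    osteophyte_lateral_femoral: int = 0
    osteophyte_inferior_acetabular: int = 0
    osteophyte_inferior_femoral: int = 0
    cysts: int = 0
    sclerosis: int = 0
    head_deformity: int = 0
    chondrocalcinosis: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in _GRADE_RANGES.items():
            v = getattr(self, name)
            if not float(v).is_integer() or not (lo <= v <= hi):
                raise ValueError(f"{name}={v!r} outside integer range {lo}-{hi}")

    @property
    def osteophyte_any(self) -> bool:
        return any(getattr(self, s) >= 1 for s in OSTEOPHYTE_SITES)

    @property
    def jsn_any(self) -> bool:
        return any(getattr(self, r) >= 1 for r in JSN_REGIONS)


@dataclass(frozen=True)
class PainOutcomes:
    """Hip pain outcomes for one participant.

    ``walking_pain_raw`` is the 0-4 walking-pain score; the binary
    walking-pain outcome is raw >= 1.  WOMAC is the 0-20 composite of
    pain, stiffness and function.
    """

    pain_internal_rotation: bool
    walking_pain_raw: int
    womac: int

    def __post_init__(self) -> None:
        if not 0 <= self.walking_pain_raw <= 4:
            raise ValueError(f"walking_pain_raw {self.walking_pain_raw} outside 0-4")
        if not 0 <= self.womac <= 20:
            raise ValueError(f"womac {self.womac} outside 0-20")

    @property
    def walking_pain(self) -> bool:
        return self.walking_pain_raw >= 1


def croft_grade(reading: RadiographReading) -> int:
    """Aggregate component grades into the 0-5 Croft grade."""
    features = [
        reading.osteophyte_any,
        reading.jsn_any,
        reading.sclerosis >= 1,
        reading.cysts >= 1,
    ]
    n_feat = sum(features)
    if n_feat >= 3:
        return 5 if reading.head_deformity >= 1 else 4
    if n_feat == 2:
        return 3
    if reading.jsn_any:
        return 2
    if reading.osteophyte_any:
        return 1
    return 0


def rhoa_case(reading: RadiographReading, threshold: int = 2) -> bool:
    """Radiographic hip OA: Croft grade at or above the threshold (2 or 3)."""
    return croft_grade(reading) >= threshold


def binary_feature(reading: RadiographReading, feature: str, min_grade: int = 1) -> bool:
    """Presence of a named component at or above a grade cut-off.

    ``feature`` is a component name (e.g. ``osteophyte_lateral_acetabular``,
    ``jsn_medial``, ``sclerosis``) or one of the pooled names
    ``osteophyte_any`` / ``jsn_any`` / ``sclerosis_any`` which test
    whether any site/region of the group reaches the cut-off.
    """
    if min_grade < 1:
        raise ValueError("min_grade must be >= 1")
    if feature == "osteophyte_any":
        return any(getattr(reading, s) >= min_grade for s in OSTEOPHYTE_SITES)
    if feature == "jsn_any":
        return any(getattr(reading, r) >= min_grade for r in JSN_REGIONS)
    if feature == "sclerosis_any":
        return reading.sclerosis >= min_grade
    if feature not in _GRADE_RANGES:
        raise KeyError(f"unknown feature {feature!r}")
    return getattr(reading, feature) >= min_grade


def prevalence(case_count: int, n: int) -> float:
    """Prevalence as a percentage rounded half-up to one decimal place."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= case_count <= n:
        raise ValueError(f"case_count {case_count} outside 0..{n}")
    pct = Decimal(100) * Decimal(case_count) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index (kg/m^2) rounded half-up to one decimal place."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    h = Decimal(str(height_cm)) / Decimal(100)
    val = Decimal(str(weight_kg)) / (h * h)
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def readings_to_frame(readings, ids=None) -> pd.DataFrame:
    """Tabulate readings (one row per image) with named grade columns."""
    cols = [f.name for f in fields(RadiographReading)]
    df = pd.DataFrame([[getattr(r, c) for c in cols] for r in readings], columns=cols)
    df.insert(0, "image_id", ids if ids is not None else np.arange(len(df)).astype(str))
    df["croft_grade"] = [croft_grade(r) for r in readings]
    return df


def frame_to_readings(df: pd.DataFrame) -> list[RadiographReading]:
    cols = [f.name for f in fields(RadiographReading)]
    return [
        RadiographReading(**{c: row[c] for c in cols if c in df.columns})
        for _, row in df.iterrows()
    ]
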