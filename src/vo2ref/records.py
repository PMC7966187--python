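"""CPET subject records: data model, CSV I/O, effort filtering, stratified summaries.

A record is one subject's maximal cycle-ergometry test: demographics,
anthropometrics, relative VO2max (ml·min⁻¹·kg⁻¹), maximum heart rate and
respiratory exchange ratio (RER).  Maximal effort is screened with the two
standard criteria — RER ≥ 1.0 and HRmax reaching at least 85% of the
age-predicted maximum (Tanaka equation, 208 − 0.7 × age) — on top of the
cohort exclusions (athletes, smokers, BMI > 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "CpetRecord",
    "EffortCriteria",
    "StratumSummary",
    "AGE_BANDS",
    "compute_bmi",
    "predicted_hrmax",
    "is_maximal_effort",
    "apply_exclusions",
    "exclusion_reason",
    "summarize_cohort",
    "sex_difference_percent",
    "age_band_label",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_exclusions_csv",
    "summaries_to_frame",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().lower()
        if v in ("male", "m"):
            return cls.MALE
        if v in ("female", "f"):
            return cls.FEMALE
        raise ValueError(f"unrecognised sex code: {value!r}")


@dataclass(frozen=True)
class CpetRecord:
    """One subject's cardiopulmonary exercise test."""

    id: str
    sex: Sex
    age: float            # years, decimal
    height: float         # cm
    weight: float         # kg
    vo2max_rel: float     # ml·min⁻¹·kg⁻¹
    hrmax: float          # beats·min⁻¹
    rer: float            # VCO2/VO2
    athlete: bool = False
    smoker: bool = False

    def __post_init__(self) -> None:
        for name in ("age", "height", "weight", "vo2max_rel", "hrmax", "rer"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be positive and finite, got {value!r}")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)


@dataclass(frozen=True)
class EffortCriteria:
    """Exclusion and maximal-effort thresholds.

    Defaults mirror standard practice: RER ≥ 1.0, HRmax ≥ 85% of the Tanaka
    prediction, BMI ≤ 30, athletes and smokers excluded.  Threshold
    comparisons on RER and HR are inclusive; the BMI rule is strict (> 30
    excluded).
    """

    rer_min: float = 1.0
    hr_fraction_min: float = 0.85
    bmi_max: float = 30.0
    exclude_athletes: bool = True
    exclude_smokers: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.hr_fraction_min <= 1):
            raise ValueError("hr_fraction_min must lie in (0, 1]")
        if self.rer_min <= 0:
            raise ValueError("rer_min must be positive")
        if self.bmi_max <= 0:
            raise ValueError("bmi_max must be positive")


# Age bands as printed on reference tables: 5–9, 10–14, 15–19, then decades,
# open-ended ≥ 60.  Edges are left-closed ([5, 10) etc.) so a decimal age of
# 9.9 sits in "5–9".
AGE_BANDS: tuple[tuple[float, float, str], ...] = (
    (5.0, 10.0, "5-9"),
    (10.0, 15.0, "10-14"),
    (15.0, 20.0, "15-19"),
    (20.0, 30.0, "20-29"),
    (30.0, 40.0, "30-39"),
    (40.0, 50.0, "40-49"),
    (50.0, 60.0, "50-59"),
    (60.0, math.inf, ">=60"),
)


def age_band_label(age: float) -> str:
    """Label of the age band containing ``age`` (left-closed edges)."""
    for lo, hi, label in AGE_BANDS:
        if lo <= age < hi:
            return label
    raise ValueError(f"age {age} outside the tabulated bands (>= 5 years)")


@dataclass(frozen=True)
class StratumSummary:
    """Mean ± SD summary of one (sex, age-band) stratum."""

    sex: Sex
    age_band: str
    n: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)   # SD omitted (absent key) when n < 2


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg·m⁻², from weight in kg and height in cm."""
    if not weight > 0:
        raise ValueError(f"weight must be positive, got {weight!r}")
    if not height > 0:
        raise ValueError(f"height must be positive, got {height!r}")
    return weight / (height / 100.0) ** 2


def predicted_hrmax(age: float) -> float:
    """Age-predicted maximum heart rate (Tanaka): 208 − 0.7 × age."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age!r}")
    return 208.0 - 0.7 * age


def is_maximal_effort(record: CpetRecord, criteria: EffortCriteria | None = None) -> bool:
    """True iff RER and heart-rate criteria are both met (inclusive)."""
    c = criteria or EffortCriteria()
    return (
        record.rer >= c.rer_min
        and record.hrmax >= c.hr_fraction_min * predicted_hrmax(record.age)
    )


def exclusion_reason(record: CpetRecord, criteria: EffortCriteria | None = None) -> str | None:
    """First failing exclusion rule, in fixed priority order, else None.

    Order: athlete, smoker, BMI, RER, HR — deterministic so reports are
    stable across runs.
    """
    c = criteria or EffortCriteria()
    if c.exclude_athletes and record.athlete:
        return "athlete"
    if c.exclude_smokers and record.smoker:
        return "smoker"
    if record.bmi > c.bmi_max:
        return "bmi"
    if record.rer < c.rer_min:
        return "rer"
    if record.hrmax < c.hr_fraction_min * predicted_hrmax(record.age):
        return "hr"
    return None


def apply_exclusions(
    records: Iterable[CpetRecord], criteria: EffortCriteria | None = None
) -> tuple[list[CpetRecord], list[tuple[CpetRecord, str]]]:
    """Partition records into (included, excluded-with-reason).

    The partition is exhaustive and disjoint; inclusion preserves input
    order; each excluded record carries the first failing rule.
    """
    c = criteria or EffortCriteria()
    included: list[CpetRecord] = []
    excluded: list[tuple[CpetRecord, str]] = []
    for rec in records:
        reason = exclusion_reason(rec, c)
        if reason is None:
            included.append(rec)
        else:
            excluded.append((rec, reason))
    return included, excluded


_SUMMARY_VARS = ("age", "weight", "height", "bmi", "vo2max_rel", "hrmax", "rer")


def summarize_cohort(records: Iterable[CpetRecord]) -> list[StratumSummary]:
    """Per (sex, age-band) n / mean / SD summaries in table order.

    SD uses the n−1 denominator and is omitted for singleton strata.
    Strata with no records are skipped.
    """
    buckets: dict[tuple[Sex, str], list[CpetRecord]] = {}
    for rec in records:
        buckets.setdefault((rec.sex, age_band_label(rec.age)), []).append(rec)

    out: list[StratumSummary] = []
    band_order = [label for _, _, label in AGE_BANDS]
    for sex in (Sex.MALE, Sex.FEMALE):
        for band in band_order:
            group = buckets.get((sex, band))
            if not group:
                continue
            means: dict[str, float] = {}
            sds: dict[str, float] = {}
            for var in _SUMMARY_VARS:
                vals = np.array([getattr(r, var) if var != "bmi" else r.bmi for r in group])
                means[var] = float(vals.mean())
                if len(vals) >= 2:
                    sds[var] = float(vals.std(ddof=1))
            out.append(StratumSummary(sex=sex, age_band=band, n=len(group), means=means, sds=sds))
    return out


def sex_difference_percent(mean_male: float, mean_female: float) -> float:
    """Male-referenced sex difference: 100 × (male − female) / male."""
    if not mean_male > 0:
        raise ValueError(f"mean_male must be positive, got {mean_male!r}")
    return 100.0 * (mean_male - mean_female) / mean_male


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: comma-separated, header required, UTF-8, dot decimals;
# sex as "male"/"female" (case-insensitive) with "M"/"F" accepted; athlete
# and smoker columns optional, defaulting to false.
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("id", "sex", "age", "height", "weight", "vo2max_rel", "hrmax", "rer")
_BOOL_TRUE = {"1", "true", "t", "yes", "y"}


def _parse_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip().lower() in _BOOL_TRUE


def read_cohort_csv(
    path: str | Path, strict_flags: bool = False
) -> tuple[list[CpetRecord], list[tuple[int, str]]]:
    """Read CPET records from CSV.

    Returns (records, row_errors); malformed rows are collected as
    (row_index, message) rather than aborting the read.  ``strict_flags``
    requires the athlete/smoker columns to be present.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"CPET CSV is missing required columns: {missing}")
    if strict_flags:
        absent = [c for c in ("athlete", "smoker") if c not in df.columns]
        if absent:
            raise ValueError(f"strict mode requires flag columns: {absent}")

    records: list[CpetRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            records.append(
                CpetRecord(
                    id=str(row["id"]),
                    sex=Sex.parse(row["sex"]),
                    age=float(row["age"]),
                    height=float(row["height"]),
                    weight=float(row["weight"]),
                    vo2max_rel=float(row["vo2max_rel"]),
                    hrmax=float(row["hrmax"]),
                    rer=float(row["rer"]),
                    athlete=_parse_flag(row.get("athlete")),
                    smoker=_parse_flag(row.get("smoker")),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((int(i), str(exc)))
    return records, errors


def records_to_frame(records: Sequence[CpetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sex": [r.sex.value for r in records],
            "age": [r.age for r in records],
            "height": [r.height for r in records],
            "weight": [r.weight for r in records],
            "vo2max_rel": [r.vo2max_rel for r in records],
            "hrmax": [r.hrmax for r in records],
            "rer": [r.rer for r in records],
            "athlete": [r.athlete for r in records],
            "smoker": [r.smoker for r in records],
        }
    )


def write_cohort_csv(records: Sequence[CpetRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_exclusions_csv(
    excluded: Sequence[tuple[CpetRecord, str]], path: str | Path
) -> None:
    df = records_to_frame([r for r, _ in excluded])
    df["reason"] = [reason for _, reason in excluded]
    df.to_csv(path, index=False)


def summaries_to_frame(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    """Flatten stratum summaries to a table mirroring the reference layout."""
    rows = []
    for s in summaries:
        row: dict = {"sex": s.sex.value, "age_band": s.age_band, "n": s.n}
        for var in _SUMMARY_VARS:
            row[f"{var}_mean"] = s.means.get(var)
            row[f"{var}_sd"] = s.sds.get(var)
        rows.append(row)
    return pd.DataFrame(rows)
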