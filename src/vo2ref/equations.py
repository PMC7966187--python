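"""Polynomial reference equations and comparison with legacy published values.

Holds this study's sex-specific polynomial reference equations for
VO2max/kg (median, lower limit of normal = P3, upper limit of normal =
P97, all in age), a registry of the legacy prediction equations commonly
used in exercise physiology (Jones; Wasserman; Cooper for children; the
SHIP/Koch equation is referenced but not reproducible from printed
values), trendline extraction from centile curves with R² and SEE, and
the model-by-age comparison table.  Absolute-VO2max equations are divided
by body weight, using the cohort's per-stratum mean weights, so every
model is compared on the ml·min⁻¹·kg⁻¹ scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import Sex, age_band_label

__all__ = [
    "Band",
    "Classification",
    "PolyEquation",
    "GoodnessOfFit",
    "PublishedModel",
    "STUDY_EQUATIONS",
    "STRATUM_MEAN_WEIGHTS",
    "COMPARISON_AGES",
    "round_half_up",
    "study_equation",
    "get_model",
    "available_models",
    "mean_weight",
    "fit_poly_trend",
    "evaluate",
    "percent_predicted",
    "classify_vs_limits",
    "comparison_table",
    "comparison_to_csv",
    "registry_to_yaml_dict",
]


class Band(str, Enum):
    MEDIAN = "median"
    LOWER_LIMIT = "lower_limit"
    UPPER_LIMIT = "upper_limit"


class Classification(str, Enum):
    BELOW_LLN = "below_lln"
    NORMAL = "normal"
    ABOVE_ULN = "above_uln"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Reference tables round half-up (48.07 → 48.1), unlike float banker's
    rounding; Decimal makes the tie rule explicit and float-safe.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PolyEquation:
    """Polynomial in age; coefficients in descending powers, constant last."""

    coefficients: tuple[float, ...]
    sex: Sex
    band: Band
    valid_age_range: tuple[float, float] = (6.0, 65.0)

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise ValueError("need at least a constant")
        if len(self.coefficients) > 1 and self.coefficients[0] == 0:
            raise ValueError("leading coefficient must be non-zero")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, age) -> float | np.ndarray:
        out = np.polyval(self.coefficients, age)
        return float(out) if np.ndim(age) == 0 else out


@dataclass(frozen=True)
class GoodnessOfFit:
    r_squared: float       # NaN when SStot = 0 (degenerate)
    see: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R² must lie in [0, 1]")
        if self.see < 0:
            raise ValueError("SEE must be non-negative")


# This study's reference equations (coefficients at printed precision).
STUDY_EQUATIONS: dict[tuple[Sex, Band], PolyEquation] = {
    (Sex.MALE, Band.MEDIAN): PolyEquation((-0.0049, 0.0884, 48.263), Sex.MALE, Band.MEDIAN),
    (Sex.MALE, Band.LOWER_LIMIT): PolyEquation(
        (0.0002, -0.0227, 0.5809, 31.909), Sex.MALE, Band.LOWER_LIMIT
    ),
    (Sex.MALE, Band.UPPER_LIMIT): PolyEquation(
        (0.00005, -0.0065, 0.0655, 64.801), Sex.MALE, Band.UPPER_LIMIT
    ),
    (Sex.FEMALE, Band.MEDIAN): PolyEquation((-0.0021, -0.1407, 43.066), Sex.FEMALE, Band.MEDIAN),
    (Sex.FEMALE, Band.LOWER_LIMIT): PolyEquation(
        (0.0017, -0.3995, 35.084), Sex.FEMALE, Band.LOWER_LIMIT
    ),
    (Sex.FEMALE, Band.UPPER_LIMIT): PolyEquation(
        (0.0001, -0.0153, 0.5674, 51.612), Sex.FEMALE, Band.UPPER_LIMIT
    ),
}


def study_equation(sex: Sex | str, band: Band | str = Band.MEDIAN) -> PolyEquation:
    return STUDY_EQUATIONS[(Sex.parse(sex), Band(band))]


# Cohort per-stratum mean weights (kg) by sex and age band, used to put
# absolute-VO2max equations on the per-kilogram scale.
STRATUM_MEAN_WEIGHTS: dict[Sex, dict[str, float]] = {
    Sex.MALE: {
        "5-9": 32.2, "10-14": 45.3, "15-19": 73.5, "20-29": 80.9,
        "30-39": 84.2, "40-49": 85.3, "50-59": 84.2, ">=60": 81.4,
    },
    Sex.FEMALE: {
        "5-9": 32.7, "10-14": 48.1, "15-19": 62.4, "20-29": 66.6,
        "30-39": 66.8, "40-49": 69.0, "50-59": 68.2, ">=60": 69.5,
    },
}

COMPARISON_AGES: tuple[float, ...] = (8, 12, 20, 30, 40, 50, 60, 70)


def mean_weight(sex: Sex | str, age: float) -> float:
    """Cohort mean weight of the (sex, age-band) stratum containing ``age``.

    Ages past the oldest band (e.g. 70) fall in the open-ended ≥ 60 band.
    """
    return STRATUM_MEAN_WEIGHTS[Sex.parse(sex)][age_band_label(age)]


# ---------------------------------------------------------------------------
# Published models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PublishedModel:
    """One published VO2max prediction model, evaluated per kilogram.

    ``needs_weight`` marks sexes whose formula predicts absolute VO2max
    (ml·min⁻¹) and must be divided by body weight.
    """

    name: str
    valid_age_range: tuple[float, float]
    needs_weight: frozenset[str] = frozenset()
    #: ages the published comparison tabulates the model at, when wider than
    #: the strict validity range (this study's polynomials are tabulated to
    #: age 70 although the cohort spans 6-65)
    table_age_range: tuple[float, float] | None = None

    def _formula(self, sex: Sex, age: float, weight: float | None) -> float:
        if self.name == "lowlands":
            return float(study_equation(sex, Band.MEDIAN)(age))
        if self.name == "jones":
            return 55.0 - 0.44 * age if sex is Sex.MALE else 43.0 - 0.36 * age
        if self.name == "wasserman":
            if sex is Sex.MALE:
                # weight × (50.72 − 0.372·age) per kg: weight cancels
                return 50.72 - 0.372 * age
            return (weight + 42.8) * (22.78 - 0.17 * age) / weight
        if self.name == "cooper":
            if sex is Sex.MALE:
                return (52.8 * weight - 303.4) / weight
            return (28.5 * weight + 288.2) / weight
        if self.name == "koch":
            raise NotImplementedError(
                "The SHIP (Koch et al.) reference equation is not reproducible "
                "from its printed table values; consult Koch et al. for the "
                "full equation."
            )
        raise KeyError(self.name)

    def predict(self, sex: Sex | str, age: float, weight: float | None = None) -> float:
        sex = Sex.parse(sex)
        if sex.value in self.needs_weight and weight is None:
            raise ValueError(
                f"model {self.name!r} needs a body weight for {sex.value} predictions"
            )
        lo, hi = self.valid_age_range
        if not (lo <= age <= hi):
            warnings.warn(
                f"age {age} outside the validity range {self.valid_age_range} "
                f"of model {self.name!r}",
                stacklevel=2,
            )
        return self._formula(sex, age, weight)

    def supports_age(self, age: float) -> bool:
        lo, hi = self.table_age_range or self.valid_age_range
        return lo <= age <= hi


_MODELS: dict[str, PublishedModel] = {
    "lowlands": PublishedModel("lowlands", (6.0, 65.0), table_age_range=(6.0, 70.0)),
    "jones": PublishedModel("jones", (20.0, 70.0)),
    "wasserman": PublishedModel("wasserman", (20.0, 70.0), needs_weight=frozenset({"female"})),
    "cooper": PublishedModel("cooper", (5.0, 18.0), needs_weight=frozenset({"male", "female"})),
    "koch": PublishedModel("koch", (25.0, 70.0)),
}


def get_model(name: str) -> PublishedModel:
    try:
        return _MODELS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(_MODELS)}") from None


def available_models() -> list[str]:
    return sorted(_MODELS)


def evaluate(
    model: PublishedModel | str, sex: Sex | str, age: float, weight: float | None = None
) -> float:
    """Predicted VO2max/kg (ml·min⁻¹·kg⁻¹) from a published model."""
    if isinstance(model, str):
        model = get_model(model)
    return model.predict(sex, age, weight)


def percent_predicted(measured: float, predicted: float) -> float:
    """Clinical percent-predicted: 100 × measured / predicted."""
    if not predicted > 0:
        raise ValueError(f"predicted must be positive, got {predicted!r}")
    if measured < 0:
        raise ValueError(f"measured must be non-negative, got {measured!r}")
    return 100.0 * measured / predicted


def classify_vs_limits(measured: float, sex: Sex | str, age: float) -> Classification:
    """Place a measurement against the P3/P97 reference limits.

    Values equal to either limit are classified normal (boundaries
    inclusive).  Ages outside 6–65 are flagged with a warning but still
    classified by polynomial extrapolation.
    """
    sex = Sex.parse(sex)
    if not (6.0 <= age <= 65.0):
        warnings.warn(f"age {age} outside the 6-65 reference range", stacklevel=2)
    lln = float(study_equation(sex, Band.LOWER_LIMIT)(age))
    uln = float(study_equation(sex, Band.UPPER_LIMIT)(age))
    if measured < lln:
        return Classification.BELOW_LLN
    if measured > uln:
        return Classification.ABOVE_ULN
    return Classification.NORMAL


# ---------------------------------------------------------------------------
# Trendline extraction
# ---------------------------------------------------------------------------


def fit_poly_trend(
    ages: Sequence[float],
    values: Sequence[float],
    degree: int,
    sex: Sex | str = Sex.MALE,
    band: Band | str = Band.MEDIAN,
) -> tuple[PolyEquation, GoodnessOfFit]:
    """Ordinary least-squares polynomial trendline with R² and SEE.

    R² = 1 − SSres/SStot; SEE = sqrt(SSres / (n − degree − 1)).  Constant
    input (SStot = 0) yields a degenerate fit flagged on the result.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be equal-length 1-D sequences")
    if len(np.unique(ages)) != len(ages):
        raise ValueError("ages must be distinct")
    if len(ages) <= degree + 1:
        raise ValueError(f"need more than degree + 1 = {degree + 1} points")

    X = np.vander(ages, degree + 1)     # descending powers, constant last
    coef, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    if rank < degree + 1:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {degree + 1}): "
            "ages do not identify the polynomial"
        )
    resid = values - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    see = math.sqrt(ss_res / (len(ages) - degree - 1))
    coef = tuple(float(c) for c in coef)
    if ss_tot == 0.0:
        gof = GoodnessOfFit(r_squared=float("nan"), see=see, degenerate=True)
        # constant input: collapse to the degree-0 equivalent
        while len(coef) > 1 and abs(coef[0]) < 1e-12:
            coef = coef[1:]
    else:
        gof = GoodnessOfFit(r_squared=max(0.0, min(1.0, 1.0 - ss_res / ss_tot)), see=see)
    eq = PolyEquation(
        coef,
        Sex.parse(sex),
        Band(band),
        valid_age_range=(float(ages.min()), float(ages.max())),
    )
    return eq, gof


# ---------------------------------------------------------------------------
# Model-by-age comparison table
# ---------------------------------------------------------------------------


def comparison_table(
    models: Sequence[PublishedModel | str] | None = None,
    ages: Sequence[float] = COMPARISON_AGES,
    weights: Mapping[tuple[str, float], float] | None = None,
) -> pd.DataFrame:
    """Model × age grid of VO2max/kg predictions, one row per (sex, model).

    Values are rounded half-up to one decimal; cells outside a model's
    validity range are left missing (printed as "x" on export).  Weights
    for absolute-VO2max models default to the cohort stratum means; a
    mapping {(sex, age): weight} overrides them.
    """
    if models is None:
        models = ["jones", "wasserman", "cooper", "lowlands"]
    resolved = [get_model(m) if isinstance(m, str) else m for m in models]
    rows = []
    for sex in (Sex.MALE, Sex.FEMALE):
        for model in resolved:
            row: dict = {"sex": sex.value, "model": model.name}
            for age in ages:
                if not model.supports_age(age):
                    row[age] = float("nan")
                    continue
                w = None
                if sex.value in model.needs_weight:
                    if weights is not None and (sex.value, age) in weights:
                        w = weights[(sex.value, age)]
                    else:
                        w = mean_weight(sex, age)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")   # tabulated ages may extrapolate
                    row[age] = round_half_up(model.predict(sex, age, w), 1)
            rows.append(row)
    return pd.DataFrame(rows)


def comparison_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Export the comparison grid with unavailable cells printed as 'x'."""
    out = table.copy()
    age_cols = [c for c in out.columns if c not in ("sex", "model")]
    for c in age_cols:
        out[c] = out[c].map(lambda v: "x" if pd.isna(v) else f"{v:.1f}")
    out.to_csv(path, index=False)


def registry_to_yaml_dict() -> dict:
    """Human-readable serialisation of the study equation registry."""
    return {
        f"{sex.value}_{band.value}": {
            "sex": sex.value,
            "band": band.value,
            "coefficients": list(eq.coefficients),
            "valid_age_range": list(eq.valid_age_range),
        }
        for (sex, band), eq in STUDY_EQUATIONS.items()
    }
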