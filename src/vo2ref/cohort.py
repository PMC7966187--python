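"""Seeded generator of registry-like synthetic CPET cohorts.

Emulates the structure of a cycle-ergometry fitness registry: roughly
3.9:1 male:female, ages 6–65 concentrated in the working decades,
per-stratum anthropometrics drawn at the cohort's published mean ± SD,
VO2max/kg drawn from an age-conditional BCCG distribution whose median
follows the study's sex-specific polynomial, HRmax scattered around the
Tanaka prediction, and an optional injected fraction of submaximal-effort
records (RER < 1.0 or HRmax below 85% of predicted) for the effort filter
to remove.  One global seed feeds per-purpose substreams, so adding a
field leaves unrelated draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .equations import study_equation
from .lms import LmsPoint, _centile
from .records import CpetRecord, Sex, predicted_hrmax

__all__ = ["BandParams", "CohortSpec", "generate_cohort", "generate_bccg"]


@dataclass(frozen=True)
class BandParams:
    """One (sex, age-band) stratum of the cohort blueprint."""

    label: str
    age_lo: float
    age_hi: float
    n: int                    # registry stratum size: sampling weight
    weight_mean: float
    weight_sd: float
    height_mean: float
    height_sd: float
    rer_mean: float


# Stratum blueprints at the registry's published composition.  Age draws are
# uniform within the band, clipped to the 6–65 study range.
_MALE_BANDS = (
    BandParams("5-9", 6, 10, 40, 32.2, 6.0, 138, 7, 1.12),
    BandParams("10-14", 10, 15, 134, 45.3, 9.8, 158, 12, 1.13),
    BandParams("15-19", 15, 20, 271, 73.5, 11.5, 181, 7, 1.16),
    BandParams("20-29", 20, 30, 1127, 80.9, 9.1, 183, 7, 1.18),
    BandParams("30-39", 30, 40, 934, 84.2, 9.6, 183, 7, 1.18),
    BandParams("40-49", 40, 50, 809, 85.3, 9.3, 183, 6, 1.14),
    BandParams("50-59", 50, 60, 324, 84.2, 8.9, 182, 6, 1.13),
    BandParams(">=60", 60, 65, 32, 81.4, 9.5, 180, 5, 1.16),
)
_FEMALE_BANDS = (
    BandParams("5-9", 6, 10, 31, 32.7, 5.0, 139, 8, 1.11),
    BandParams("10-14", 10, 15, 96, 48.1, 11.6, 159, 10, 1.15),
    BandParams("15-19", 15, 20, 74, 62.4, 7.3, 171, 6, 1.15),
    BandParams("20-29", 20, 30, 244, 66.6, 7.7, 171, 6, 1.13),
    BandParams("30-39", 30, 40, 246, 66.8, 8.9, 170, 6, 1.13),
    BandParams("40-49", 40, 50, 164, 69.0, 8.3, 170, 6, 1.14),
    BandParams("50-59", 50, 60, 76, 68.2, 8.7, 168, 6, 1.16),
    BandParams(">=60", 60, 65, 10, 69.5, 5.3, 168, 6, 1.17),
)

_N_MALE = sum(b.n for b in _MALE_BANDS)      # 3671
_N_FEMALE = sum(b.n for b in _FEMALE_BANDS)  # 941


def _default_m_curve(sex: Sex) -> Callable[[np.ndarray], np.ndarray]:
    eq = study_equation(sex)
    return lambda a: np.polyval(eq.coefficients, a)


@dataclass(frozen=True)
class CohortSpec:
    """Blueprint for one synthetic cohort draw.

    Defaults reproduce the registry's composition: n = 4612 with male
    fraction 3671/4612, band counts proportional to the published strata,
    generating median curves equal to the study's sex-specific polynomials
    with S = 0.18 (males) / 0.23 (females) and L = 1 (no skew — the true
    registry skewness is unknowable, so the generator defaults symmetric
    and exposes the knob).  ``submaximal_fraction`` injects records that
    fail the effort screen; ``rer_fail_share`` of those fail on RER, the
    rest on heart rate.  ``vo2_shift`` adds a constant to every generated
    VO2max/kg (fitness-bias / injected-offset experiments).
    """

    n: int = _N_MALE + _N_FEMALE
    male_fraction: float = _N_MALE / (_N_MALE + _N_FEMALE)
    submaximal_fraction: float = 0.0
    rer_fail_share: float = 0.5
    s_male: float = 0.18
    s_female: float = 0.23
    l: float = 1.0
    vo2_shift: float = 0.0
    hr_sd: float = 10.0
    rer_sd: float = 0.08
    seed: int = 0
    m_curve_male: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: _default_m_curve(Sex.MALE)
    )
    m_curve_female: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: _default_m_curve(Sex.FEMALE)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("male_fraction", "submaximal_fraction", "rer_fail_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("s_male", "s_female", "hr_sd", "rer_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _truncated_normal(
    rng: np.random.Generator, mean, sd, lower: float, n: int
) -> np.ndarray:
    """Elementwise normal draws redrawn until strictly above ``lower``."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (n,))
    out = mean + sd * rng.standard_normal(n)
    bad = out <= lower if np.isscalar(lower) else out <= lower
    for _ in range(1000):
        if not np.any(bad):
            break
        out[bad] = mean[bad] + sd * rng.standard_normal(int(bad.sum()))
        bad = out <= lower
    return out


def generate_cohort(spec: CohortSpec) -> list[CpetRecord]:
    """Draw one synthetic cohort; byte-identical for identical spec + seed."""
    ss = np.random.SeedSequence(spec.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("sex", "band", "age", "height", "weight", "vo2", "hr", "rer", "submax"),
            ss.spawn(9),
        )
    }
    n = spec.n
    is_male = streams["sex"].random(n) < spec.male_fraction

    bands_by_sex = {True: _MALE_BANDS, False: _FEMALE_BANDS}
    band_idx = np.empty(n, dtype=int)
    for male in (True, False):
        mask = is_male == male
        bands = bands_by_sex[male]
        probs = np.array([b.n for b in bands], dtype=float)
        probs /= probs.sum()
        band_idx[mask] = streams["band"].choice(len(bands), size=int(mask.sum()), p=probs)

    def band_of(i: int) -> BandParams:
        return bands_by_sex[bool(is_male[i])][band_idx[i]]

    lo = np.array([band_of(i).age_lo for i in range(n)])
    hi = np.array([band_of(i).age_hi for i in range(n)])
    ages = lo + (hi - lo) * streams["age"].random(n)

    h_mean = np.array([band_of(i).height_mean for i in range(n)])
    h_sd = np.array([band_of(i).height_sd for i in range(n)])
    heights = h_mean + h_sd * streams["height"].standard_normal(n)
    heights = np.maximum(heights, 50.0)   # physical floor; draws never get near it

    # Registry pre-excluded BMI > 30, so weights are redrawn until BMI ≤ 30.
    w_mean = np.array([band_of(i).weight_mean for i in range(n)])
    w_sd = np.array([band_of(i).weight_sd for i in range(n)])
    weights = w_mean + w_sd * streams["weight"].standard_normal(n)
    bad = (weights <= 0) | (weights / (heights / 100.0) ** 2 > 30.0)
    for _ in range(1000):
        if not np.any(bad):
            break
        weights[bad] = w_mean[bad] + w_sd[bad] * streams["weight"].standard_normal(int(bad.sum()))
        bad = (weights <= 0) | (weights / (heights / 100.0) ** 2 > 30.0)

    m_vals = np.where(
        is_male, spec.m_curve_male(ages), spec.m_curve_female(ages)
    ).astype(float)
    s_vals = np.where(is_male, spec.s_male, spec.s_female)
    l_vals = np.full(n, spec.l)
    rng_v = streams["vo2"]
    z = rng_v.standard_normal(n)
    bad = 1.0 + l_vals * s_vals * z <= 0
    for _ in range(1000):
        if not np.any(bad):
            break
        z[bad] = rng_v.standard_normal(int(bad.sum()))
        bad = 1.0 + l_vals * s_vals * z <= 0
    vo2 = _centile(z, l_vals, m_vals, s_vals) + spec.vo2_shift
    vo2 = np.maximum(vo2, 1.0)   # guard against pathological shifts

    u = streams["submax"].random(2 * n)
    submax = u[:n] < spec.submaximal_fraction
    fail_rer = submax & (u[n:] < spec.rer_fail_share)
    fail_hr = submax & ~fail_rer

    tanaka = predicted_hrmax(0) - 0.7 * ages   # vectorised 208 − 0.7·age
    hr_thresh = 0.85 * tanaka
    rng_hr = streams["hr"]
    hr = tanaka + spec.hr_sd * rng_hr.standard_normal(n)
    bad = ~fail_hr & (hr < hr_thresh)
    for _ in range(1000):
        if not np.any(bad):
            break
        hr[bad] = tanaka[bad] + spec.hr_sd * rng_hr.standard_normal(int(bad.sum()))
        bad = ~fail_hr & (hr < hr_thresh)
    # records meant to fail on heart rate: uniform 60–84.9% of predicted
    hr = np.where(fail_hr, (0.60 + 0.249 * rng_hr.random(n)) * tanaka, hr)

    rer_mean = np.array([band_of(i).rer_mean for i in range(n)])
    rng_rer = streams["rer"]
    rer = _truncated_normal(rng_rer, rer_mean, spec.rer_sd, 0.999999, n)
    rer = np.where(fail_rer, 0.85 + 0.14 * rng_rer.random(n), rer)

    records = []
    for i in range(n):
        records.append(
            CpetRecord(
                id=f"syn{i:05d}",
                sex=Sex.MALE if is_male[i] else Sex.FEMALE,
                age=float(ages[i]),
                height=float(heights[i]),
                weight=float(weights[i]),
                vo2max_rel=float(vo2[i]),
                hrmax=float(hr[i]),
                rer=float(rer[i]),
            )
        )
    return records


def generate_bccg(
    point,
    n: int,
    seed: int,
    age_range: tuple[float, float] = (6.0, 65.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(age, y) pairs from the BCCG along smooth (or constant) curves.

    ``point`` is either an :class:`~vo2ref.lms.LmsPoint` (constant curves:
    i.i.d. draws) or a triple of callables (l(age), m(age), s(age)).
    Ages are uniform on ``age_range``; seeded and reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng_age, rng_y = (np.random.default_rng(c) for c in ss.spawn(2))
    ages = age_range[0] + (age_range[1] - age_range[0]) * rng_age.random(n)
    if isinstance(point, LmsPoint):
        l = np.full(n, point.l)
        m = np.full(n, point.m)
        s = np.full(n, point.s)
    else:
        l_fn, m_fn, s_fn = point
        l, m, s = (np.asarray(f(ages), dtype=float) for f in (l_fn, m_fn, s_fn))
    z = rng_y.standard_normal(n)
    bad = 1.0 + l * s * z <= 0
    for _ in range(1000):
        if not np.any(bad):
            break
        z[bad] = rng_y.standard_normal(int(bad.sum()))
        bad = 1.0 + l * s * z <= 0
    return ages, _centile(z, l, m, s)
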