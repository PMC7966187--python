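"""The LMS (Box-Cox Cole-Green) conditional distribution and its fitting.

The LMS method summarises how a positive measurement's distribution changes
with age through three smooth curves: the Box-Cox power L(t) capturing
skewness, the median M(t), and the generalised coefficient of variation
S(t).  Conditional on age t, a measurement y has z-score

    z = ((y/M)^L − 1) / (L·S)        (L ≠ 0)
    z = ln(y/M) / S                  (L = 0)

which is treated as standard normal; centile curves are the inverse
transform evaluated at normal quantiles.  The three curves are fitted as
cubic splines by maximising the penalised log-likelihood

    Σ_i log f(y_i | L(t_i), M(t_i), S(t_i))
        − λ_L ∫ L″² − λ_M ∫ M″² − λ_S ∫ S″²

with Fisher-scoring backfitting over the L, M and S coefficient blocks.
The sample truncation of z (the transform requires 1 + L·S·z > 0) is
ignored in the likelihood, which is negligible for S ≪ 1 as is the case for
physiological measurements such as VO2max/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from scipy.interpolate import BSpline

__all__ = [
    "L_EPS",
    "LmsPoint",
    "LmsCurve",
    "LmsCurveSet",
    "FitConfig",
    "CentileTable",
    "lms_zscore",
    "lms_centile",
    "lms_logdensity",
    "lms_sample",
    "fit_lms",
    "centile_table",
]

# Switch to the L → 0 logarithmic limit below this magnitude; keeps the
# transform continuous to ~1e−10 across the switch.
L_EPS = 1e-5

DEFAULT_PERCENTILES = (3.0, 10.0, 25.0, 50.0, 75.0, 90.0, 97.0)


@dataclass(frozen=True)
class LmsPoint:
    """The (L, M, S) triple at a single age."""

    l: float
    m: float
    s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.l)):
            raise ValueError(f"L must be finite, got {self.l!r}")
        if not (self.m > 0 and math.isfinite(self.m)):
            raise ValueError(f"M must be positive, got {self.m!r}")
        if not (self.s > 0 and math.isfinite(self.s)):
            raise ValueError(f"S must be positive, got {self.s!r}")


# ---------------------------------------------------------------------------
# Transforms and density (vectorised internals, scalar-friendly API)
# ---------------------------------------------------------------------------


def _zscore(y, l, m, s):
    y, l, m, s = np.broadcast_arrays(y, l, m, s)
    ratio = np.asarray(y, dtype=float) / m
    logr = np.log(ratio)
    with np.errstate(over="ignore"):
        z_pow = (np.power(ratio, l) - 1.0) / (np.where(np.abs(l) < L_EPS, 1.0, l) * s)
    z_log = logr / s
    return np.where(np.abs(l) < L_EPS, z_log, z_pow)


def lms_zscore(y: float, point: LmsPoint) -> float:
    """Age-conditional z-score of measurement ``y`` under (L, M, S)."""
    if not np.all(np.asarray(y) > 0):
        raise ValueError(f"y must be positive, got {y!r}")
    out = _zscore(y, point.l, point.m, point.s)
    return float(out) if np.ndim(y) == 0 else out


def _centile(z, l, m, s):
    z, l, m, s = np.broadcast_arrays(np.asarray(z, dtype=float), l, m, s)
    base = 1.0 + l * s * z
    small = np.abs(l) < L_EPS
    if np.any(~small & (base <= 0)):
        raise ValueError("centile undefined: 1 + L·S·z must be positive")
    with np.errstate(invalid="ignore"):
        y_pow = m * np.power(np.where(small, 1.0, base), 1.0 / np.where(small, 1.0, l))
    y_log = m * np.exp(s * z)
    return np.where(small, y_log, y_pow)


def lms_centile(z: float, point: LmsPoint) -> float:
    """Inverse transform: measurement at z-score ``z`` under (L, M, S)."""
    out = _centile(z, point.l, point.m, point.s)
    return float(out) if np.ndim(z) == 0 else out


def _logdensity(y, l, m, s):
    # change of variables y -> z: |dz/dy| = (y/M)^(L-1)/(S·M)
    z = _zscore(y, l, m, s)
    y = np.asarray(y, dtype=float)
    return (l - 1.0) * np.log(y / m) - np.log(s * m) - 0.5 * z**2 - 0.5 * math.log(2 * math.pi)


def lms_logdensity(y: float, point: LmsPoint) -> float:
    """Log-density of the BCCG distribution at ``y`` (truncation ignored)."""
    if not np.all(np.asarray(y) > 0):
        raise ValueError(f"y must be positive, got {y!r}")
    out = _logdensity(y, point.l, point.m, point.s)
    return float(out) if np.ndim(y) == 0 else out


def lms_sample(
    point: LmsPoint, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` BCCG variates: z ~ N(0,1) subject to 1 + L·S·z > 0.

    Violating draws are rejected and redrawn (exceedingly rare for S ≪ 1).
    Accepts either an integer seed or a Generator for substream control.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n)
    if abs(point.l) >= L_EPS:
        bad = 1.0 + point.l * point.s * z <= 0
        while np.any(bad):
            z[bad] = rng.standard_normal(int(bad.sum()))
            bad = 1.0 + point.l * point.s * z <= 0
    return _centile(z, point.l, point.m, point.s)


# ---------------------------------------------------------------------------
# Cubic-spline curves and the roughness penalty
# ---------------------------------------------------------------------------


class _SplineBasis:
    """Cubic B-spline basis on [lo, hi] with the ∫c″² roughness penalty."""

    def __init__(self, lo: float, hi: float, n_inner_knots: int = 8):
        if not hi > lo:
            raise ValueError("degenerate age range")
        self.lo, self.hi = float(lo), float(hi)
        k = 3
        inner = np.linspace(lo, hi, n_inner_knots + 2)[1:-1]
        self.knots = np.concatenate([[lo] * (k + 1), inner, [hi] * (k + 1)])
        self.degree = k
        self.size = len(self.knots) - k - 1
        self._penalty: np.ndarray | None = None

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self) -> np.ndarray:
        """P with θᵀPθ = ∫ c″(x)² dx; 3-point Gauss-Legendre per interval
        (exact: the integrand is piecewise quartic)."""
        if self._penalty is not None:
            return self._penalty
        k, t, p = self.degree, self.knots, self.size
        nodes, weights = np.polynomial.legendre.leggauss(3)
        xs, ws = [], []
        breaks = np.unique(t)
        for a, b in zip(breaks[:-1], breaks[1:]):
            xs.append(0.5 * (b - a) * nodes + 0.5 * (a + b))
            ws.append(0.5 * (b - a) * weights)
        xq = np.concatenate(xs)
        wq = np.concatenate(ws)
        G = np.empty((len(xq), p))
        for j in range(p):
            coef = np.zeros(p)
            coef[j] = 1.0
            G[:, j] = BSpline(t, coef, k, extrapolate=False).derivative(2)(xq)
        self._penalty = G.T @ (wq[:, None] * G)
        return self._penalty

    def lambda_for_edf(self, target_edf: float, weights: np.ndarray, B: np.ndarray) -> float:
        """Penalty giving tr[(BᵀWB + 2λP)⁻¹BᵀWB] ≈ target_edf (bisection)."""
        P = self.penalty()
        BtWB = B.T @ (weights[:, None] * B)

        def edf(log_lam: float) -> float:
            lam = 10.0**log_lam
            return float(np.trace(np.linalg.solve(BtWB + 2 * lam * P, BtWB)))

        lo_l, hi_l = -8.0, 12.0
        if edf(lo_l) < target_edf:       # basis too small to reach target
            return 10.0**lo_l
        if edf(hi_l) > target_edf:
            return 10.0**hi_l
        for _ in range(80):
            mid = 0.5 * (lo_l + hi_l)
            if edf(mid) > target_edf:
                lo_l = mid
            else:
                hi_l = mid
        return 10.0 ** (0.5 * (lo_l + hi_l))


@dataclass(frozen=True)
class LmsCurve:
    """One fitted curve: a cubic spline, or a constant when fully smoothed."""

    basis: _SplineBasis | None
    coef: np.ndarray | None
    constant: float | None = None

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.constant is not None:
            return np.full(x.shape, self.constant)
        return self.basis.design(np.atleast_1d(x)).dot(self.coef).reshape(x.shape)


@dataclass
class LmsCurveSet:
    """Age-smooth L, M, S curves with the grid they were evaluated on."""

    age_grid: np.ndarray
    curve_l: Callable[[np.ndarray], np.ndarray]
    curve_m: Callable[[np.ndarray], np.ndarray]
    curve_s: Callable[[np.ndarray], np.ndarray]
    age_range: tuple[float, float]
    sex: str | None = None
    edf: dict = field(default_factory=dict)
    lambdas: dict = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    penalized_loglik: float = float("nan")
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        grid = np.asarray(self.age_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("age_grid must be strictly increasing")
        self.age_grid = grid
        l, m, s = self.evaluate(grid)
        if np.any(m <= 0) or np.any(s <= 0):
            raise ValueError("M and S must be positive over the age grid")

    def evaluate(self, ages) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ages = np.asarray(ages, dtype=float)
        return self.curve_l(ages), self.curve_m(ages), self.curve_s(ages)

    def point(self, age: float) -> LmsPoint:
        l, m, s = self.evaluate(np.atleast_1d(float(age)))
        return LmsPoint(float(l[0]), float(m[0]), float(s[0]))

    def to_frame(self) -> pd.DataFrame:
        l, m, s = self.evaluate(self.age_grid)
        return pd.DataFrame({"age": self.age_grid, "L": l, "M": m, "S": s})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex: str | None = None) -> "LmsCurveSet":
        """Rebuild a curve set from an (age, L, M, S) table by interpolation."""
        ages = np.asarray(df["age"], dtype=float)
        rng = (float(ages.min()), float(ages.max()))

        def interp(col: str) -> Callable[[np.ndarray], np.ndarray]:
            f = interpolate.PchipInterpolator(ages, np.asarray(df[col], dtype=float))
            return lambda x: f(np.clip(x, rng[0], rng[1]))

        return cls(
            age_grid=ages,
            curve_l=interp("L"),
            curve_m=interp("M"),
            curve_s=interp("S"),
            age_range=rng,
            sex=sex,
        )


@dataclass(frozen=True)
class FitConfig:
    """Smoothing and iteration settings for :func:`fit_lms`.

    Smoothing is given either as explicit penalties (``lambda_l`` etc.;
    ``inf`` collapses the curve to a constant) or as target effective
    degrees of freedom, translated to penalties at initialisation.  The
    defaults (EDF 3/5/3 for L/M/S) suit a single smooth covariate over a
    narrow age range; they are configuration, not constants of the method.
    ``fix_l`` holds the Box-Cox power at a given value (common chart-making
    practice when skewness is weak or unidentifiable).
    """

    edf_l: float = 3.0
    edf_m: float = 5.0
    edf_s: float = 3.0
    lambda_l: float | None = None
    lambda_m: float | None = None
    lambda_s: float | None = None
    fix_l: float | None = None
    l_init: float = 1.0
    n_inner_knots: int = 8
    max_iter: int = 50
    tol: float = 1e-3
    grid_step: float = 0.5

    def __post_init__(self) -> None:
        for lam in (self.lambda_l, self.lambda_m, self.lambda_s):
            if lam is not None and lam < 0:
                raise ValueError("penalties must be >= 0")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


# --- scores and Fisher weights per observation -----------------------------


def _scores(y, l, m, s):
    """Per-observation score ∂ℓ/∂(L, M, S) and Fisher-type weights.

    Closed forms follow from the BCCG log-density; the L-score uses its
    analytic L → 0 limit below L_EPS.  Weights are approximate expected
    information terms — positive by construction, which is all Fisher
    scoring with step-halving requires.
    """
    z = _zscore(y, l, m, s)
    t = np.log(np.asarray(y, dtype=float) / m)
    small = np.abs(l) < L_EPS
    u_m = (z / s + l * (z**2 - 1.0)) / m
    u_s = (z**2 - 1.0) / s
    with np.errstate(divide="ignore", invalid="ignore"):
        lsz = 1.0 + l * s * z
        u_l_full = t - z * t * lsz / (np.where(small, 1.0, l) * s) + z**2 / np.where(small, 1.0, l)
    u_l_limit = t - t**3 / (2.0 * s**2)
    u_l = np.where(small, u_l_limit, u_l_full)
    w_m = (1.0 / s**2 + 2.0 * l**2) / m**2
    w_s = 2.0 / s**2
    w_l = 1.75 * s**2
    return (u_l, u_m, u_s), (w_l, w_m, w_s)


def _penalized_loglik(y, l, m, s, thetas, lams, pen):
    if np.any(m <= 0) or np.any(s <= 0):
        return -np.inf
    ll = float(np.sum(_logdensity(y, l, m, s)))
    for key in ("l", "m", "s"):
        th, lam = thetas[key], lams[key]
        if th is not None and lam is not None and np.isfinite(lam) and lam > 0:
            ll -= lam * float(th @ pen @ th)
    return ll


def _ridge_fit(B: np.ndarray, target: np.ndarray, P: np.ndarray, lam: float) -> np.ndarray:
    lam_eff = 0.0 if not np.isfinite(lam) else lam
    A = B.T @ B + 2 * lam_eff * P + 1e-8 * np.eye(B.shape[1])
    return np.linalg.solve(A, B.T @ target)


def fit_lms(
    ages: Sequence[float],
    y: Sequence[float],
    config: FitConfig | None = None,
    sex: str | None = None,
) -> LmsCurveSet:
    """Fit age-smooth L, M, S curves by penalised-likelihood backfitting.

    The outer loop cycles M → S → L; each block takes one Fisher-scoring
    step (score from the BCCG log-density, approximate expected-information
    weights) with step-halving so the penalised log-likelihood never
    decreases across accepted iterations.  Non-convergence within
    ``max_iter`` is flagged on the result, not raised.
    """
    cfg = config or FitConfig()
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.shape != y.shape or ages.ndim != 1:
        raise ValueError("ages and y must be equal-length 1-D sequences")
    if len(ages) < 50:
        raise ValueError("fit_lms requires at least 50 records")
    if len(np.unique(ages)) < 3:
        raise ValueError("degenerate input: need at least 3 distinct ages")
    if np.any(y <= 0):
        raise ValueError("y must be positive")

    lo, hi = float(ages.min()), float(ages.max())
    basis = _SplineBasis(lo, hi, cfg.n_inner_knots)
    B = basis.design(ages)
    P = basis.penalty()
    ones = np.ones(len(ages))

    # --- initialisation: L = l_init, M = windowed running median,
    #     S = windowed SD / median --------------------------------------
    n_bins = int(np.clip(len(ages) // 100, 6, 14))
    qs = np.quantile(ages, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    centers, med, cv = [], [], []
    for a, b in zip(qs[:-1], qs[1:]):
        mask = (ages >= a) & (ages < b)
        if mask.sum() < 5:
            continue
        yy = y[mask]
        m_b = float(np.median(yy))
        centers.append(float(ages[mask].mean()))
        med.append(m_b)
        cv.append(float(np.std(yy, ddof=1) / m_b) if mask.sum() > 1 else 0.1)
    centers = np.asarray(centers)
    Bc = basis.design(centers)

    def init_block(values: np.ndarray, lam: float, constant: bool) -> np.ndarray | float:
        if constant:
            return float(np.mean(values))
        return _ridge_fit(Bc, np.asarray(values), P, lam)

    # Resolve smoothing: explicit λ wins; otherwise translate target EDF.
    # EDF ≤ 1 or λ = inf collapses the curve to a constant.
    def resolve(lam: float | None, edf: float, w_scale: np.ndarray) -> tuple[float, bool]:
        if lam is not None:
            return float(lam), not np.isfinite(lam)
        if edf <= 1.0:
            return float("inf"), True
        return basis.lambda_for_edf(edf, w_scale, B), False

    m0 = np.interp(ages, centers, med)
    s0 = np.interp(ages, centers, cv)
    (_, _, _), (w_l0, w_m0, w_s0) = _scores(y, np.full_like(y, cfg.l_init), m0, np.maximum(s0, 1e-3))

    lam_m, const_m = resolve(cfg.lambda_m, cfg.edf_m, w_m0)
    lam_s, const_s = resolve(cfg.lambda_s, cfg.edf_s, w_s0)
    if cfg.fix_l is not None:
        lam_l, const_l = float("inf"), True
    else:
        lam_l, const_l = resolve(cfg.lambda_l, cfg.edf_l, np.full_like(y, np.mean(w_l0)))

    theta = {
        "m": init_block(med, lam_m, const_m),
        "s": init_block(np.maximum(cv, 1e-3), lam_s, const_s),
        "l": cfg.l_init if (const_l or cfg.fix_l is not None) else _ridge_fit(
            basis.design(ages), np.full(len(ages), cfg.l_init), P, lam_l
        ),
    }
    if cfg.fix_l is not None:
        theta["l"] = float(cfg.fix_l)
    constant = {"l": const_l, "m": const_m, "s": const_s}
    lams = {"l": lam_l, "m": lam_m, "s": lam_s}

    def curve_values(key: str) -> np.ndarray:
        th = theta[key]
        return np.full(len(ages), th) if constant[key] else B @ th

    def spline_thetas() -> dict:
        return {k: (None if constant[k] else theta[k]) for k in ("l", "m", "s")}

    def pll() -> float:
        return _penalized_loglik(
            y, curve_values("l"), curve_values("m"), curve_values("s"), spline_thetas(), lams, P
        )

    current = pll()
    if not np.isfinite(current):
        raise RuntimeError("initialisation produced an invalid likelihood")
    trace = [current]
    score_index = {"l": 0, "m": 1, "s": 2}

    def fisher_step(key: str) -> float:
        """One step-halved Fisher update of a block; returns new pll."""
        nonlocal current
        if key == "l" and cfg.fix_l is not None:
            return current
        l_v, m_v, s_v = curve_values("l"), curve_values("m"), curve_values("s")
        (scores, weights) = _scores(y, l_v, m_v, s_v)
        u, w = scores[score_index[key]], weights[score_index[key]]
        lam = lams[key]
        if constant[key]:
            g = float(np.sum(u))
            h = float(np.sum(w))
            delta = g / h
        else:
            g = B.T @ u - 2 * lam * (P @ theta[key])
            H = B.T @ (w[:, None] * B) + 2 * lam * P + 1e-10 * np.eye(basis.size)
            delta = np.linalg.solve(H, g)
        old = theta[key]
        step = 1.0
        for _ in range(30):
            theta[key] = old + step * delta
            candidate = pll()
            if np.isfinite(candidate) and candidate >= current - 1e-12:
                current = max(candidate, current)
                return current
            step *= 0.5
        theta[key] = old     # no improving step found; keep the block
        return current

    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        before = current
        for key in ("m", "s", "l"):
            fisher_step(key)
        trace.append(current)
        if current - before < cfg.tol:
            converged = True
            break

    def make_curve(key: str) -> LmsCurve:
        if constant[key]:
            return LmsCurve(basis=None, coef=None, constant=float(theta[key]))
        return LmsCurve(basis=basis, coef=np.asarray(theta[key]))

    grid = np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)
    result = LmsCurveSet(
        age_grid=grid,
        curve_l=make_curve("l"),
        curve_m=make_curve("m"),
        curve_s=make_curve("s"),
        age_range=(lo, hi),
        sex=sex,
        edf={"l": cfg.edf_l, "m": cfg.edf_m, "s": cfg.edf_s},
        lambdas=dict(lams),
        converged=converged,
        n_iter=iterations,
        penalized_loglik=current,
        loglik_trace=trace,
    )
    return result


# ---------------------------------------------------------------------------
# Centile tables
# ---------------------------------------------------------------------------


@dataclass
class CentileTable:
    """Percentile values over an age grid; rows increase with percentile."""

    age_grid: np.ndarray
    percentiles: tuple[float, ...]
    values: np.ndarray                 # shape (n_ages, n_percentiles)
    extrapolated: np.ndarray           # bool per age: outside the fitted range
    sex: str | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values, axis=1) <= 0):
            raise ValueError("centile values must increase strictly with percentile")

    def column(self, p: float) -> np.ndarray:
        return self.values[:, self.percentiles.index(p)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"P{p:g}" for p in self.percentiles]
        )
        df.insert(0, "age", self.age_grid)
        df["extrapolated"] = self.extrapolated
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sex: str | None = None) -> "CentileTable":
        df = pd.read_csv(path)
        pcols = [c for c in df.columns if c.startswith("P")]
        pcts = tuple(float(c[1:]) for c in pcols)
        extrap = (
            df["extrapolated"].to_numpy(dtype=bool)
            if "extrapolated" in df
            else np.zeros(len(df), dtype=bool)
        )
        return cls(
            age_grid=df["age"].to_numpy(dtype=float),
            percentiles=pcts,
            values=df[pcols].to_numpy(dtype=float),
            extrapolated=extrap,
            sex=sex,
        )


def centile_table(
    curves: LmsCurveSet,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    age_grid: Sequence[float] | None = None,
) -> CentileTable:
    """Evaluate centile curves at exact standard-normal quantiles.

    value(age, p) = lms_centile(Φ⁻¹(p/100), (L, M, S)(age)).  Ages beyond
    the fitted range are evaluated at the clamped curve ends and flagged.
    """
    pcts = tuple(float(p) for p in percentiles)
    if any(not (0 < p < 100) for p in pcts):
        raise ValueError("percentiles must lie strictly inside (0, 100)")
    grid = np.asarray(age_grid if age_grid is not None else curves.age_grid, dtype=float)
    l, m, s = curves.evaluate(grid)
    zs = stats.norm.ppf(np.asarray(pcts) / 100.0)
    values = np.column_stack([_centile(np.full_like(grid, z), l, m, s) for z in zs])
    lo, hi = curves.age_range
    extrap = (grid < lo) | (grid > hi)
    return CentileTable(
        age_grid=grid, percentiles=pcts, values=values, extrapolated=extrap, sex=curves.sex
    )
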