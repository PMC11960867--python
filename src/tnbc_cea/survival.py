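"""Parametric survival curves and censored maximum-likelihood fitting.

Five accelerated-failure-time families are supported — exponential, Weibull,
Gompertz, lognormal and loglogistic — all parameterized with a rate-like
``lambda_`` (per month) and a dimensionless shape ``gamma_`` so that a single
(λ, γ) pair describes any curve.  Time is measured in months throughout.

Loglogistic conventions
-----------------------
Published loglogistic fits are ambiguous about what "γ" means.  Two
conventions share the same median 1/λ but differ sharply in the tail:

* ``"aft_scale"`` (default): S(t) = [1 + (λt)^(1/γ)]⁻¹ — γ is the AFT scale
  parameter σ as reported by Stata's ``streg, distribution(llogistic)``; the
  shape exponent is p = 1/γ.
* ``"exponent"``: S(t) = [1 + (λt)^γ]⁻¹ — γ is the shape exponent itself.

The third reading, S(t) = [1 + λ·t^γ]⁻¹, is not offered: its median
(1/λ)^(1/γ) lands at hundreds of months for the curve sets this package
ships with, far from the trial medians those curves must reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "ParametricFamily",
    "SurvivalParams",
    "IPDRecord",
    "FitResult",
    "FamilyComparison",
    "survival_at",
    "median_survival",
    "fit_aft",
    "aic",
    "compare_families",
    "DegenerateDataError",
    "ConvergenceError",
]

_MONTH_DAYS = 30.4375  # 365.25 / 12

LL_AFT_SCALE = "aft_scale"
LL_EXPONENT = "exponent"


class ParametricFamily(str, Enum):
    """The five candidate AFT families."""

    exponential = "exponential"
    weibull = "weibull"
    gompertz = "gompertz"
    lognormal = "lognormal"
    loglogistic = "loglogistic"


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify the parameters (e.g. no events)."""


class ConvergenceError(RuntimeError):
    """Raised when the multi-start optimizer fails to converge."""


@dataclass(frozen=True)
class SurvivalParams:
    """One parametric survival curve.

    Parameters
    ----------
    family : ParametricFamily
    lambda_ : float
        Positive rate-like parameter, per month.
    gamma_ : float
        Positive shape parameter (ignored by the exponential family).
    ll_convention : str
        Loglogistic γ convention, ``"aft_scale"`` or ``"exponent"``;
        irrelevant for the other families.
    """

    family: ParametricFamily
    lambda_: float
    gamma_: float = 1.0
    ll_convention: str = LL_AFT_SCALE

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ParametricFamily(self.family))
        if not (self.lambda_ > 0 and math.isfinite(self.lambda_)):
            raise ValueError(f"lambda_ must be positive and finite, got {self.lambda_}")
        if not (self.gamma_ > 0 and math.isfinite(self.gamma_)):
            raise ValueError(f"gamma_ must be positive and finite, got {self.gamma_}")
        if self.ll_convention not in (LL_AFT_SCALE, LL_EXPONENT):
            raise ValueError(f"unknown loglogistic convention {self.ll_convention!r}")

    @property
    def n_free_params(self) -> int:
        return 1 if self.family is ParametricFamily.exponential else 2

    def _ll_shape(self) -> float:
        """Loglogistic shape exponent p under the active convention."""
        return 1.0 / self.gamma_ if self.ll_convention == LL_AFT_SCALE else self.gamma_


@dataclass(frozen=True)
class IPDRecord:
    """One (pseudo-)patient: follow-up time in months and event indicator."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0 or not math.isfinite(self.time):
            raise ValueError(f"time must be finite and >= 0, got {self.time}")


def _as_arrays(ipd: Iterable[IPDRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(ipd)
    t = np.asarray([r.time for r in recs], dtype=float)
    e = np.asarray([bool(r.event) for r in recs], dtype=bool)
    return t, e


def survival_at(params: SurvivalParams, t):
    """Survivor function S(t), vectorized over ``t`` (months)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    lam, gam = params.lambda_, params.gamma_
    with np.errstate(over="ignore", divide="ignore"):
        if params.family is ParametricFamily.exponential:
            s = np.exp(-lam * t_arr)
        elif params.family is ParametricFamily.weibull:
            s = np.exp(-((lam * t_arr) ** gam))
        elif params.family is ParametricFamily.gompertz:
            s = np.exp(-(lam / gam) * np.expm1(gam * t_arr))
        elif params.family is ParametricFamily.lognormal:
            # S(t) = 1 - Φ(γ·ln(λt)); median 1/λ, σ = 1/γ on the log scale.
            z = np.where(t_arr > 0, gam * np.log(np.maximum(lam * t_arr, 1e-300)), -np.inf)
            s = special.ndtr(-z)
        elif params.family is ParametricFamily.loglogistic:
            p = params._ll_shape()
            s = 1.0 / (1.0 + (lam * t_arr) ** p)
        else:  # pragma: no cover
            raise ValueError(params.family)
    s = np.where(t_arr == 0.0, 1.0, s)
    return float(s) if np.isscalar(t) or t_arr.ndim == 0 else s


def _log_pdf(params: SurvivalParams, t: np.ndarray) -> np.ndarray:
    """log f(t) for event times (t > 0 assumed)."""
    lam, gam = params.lambda_, params.gamma_
    logt = np.log(t)
    if params.family is ParametricFamily.exponential:
        return math.log(lam) - lam * t
    if params.family is ParametricFamily.weibull:
        return math.log(gam) + gam * math.log(lam) + (gam - 1.0) * logt - (lam * t) ** gam
    if params.family is ParametricFamily.gompertz:
        return math.log(lam) + gam * t - (lam / gam) * np.expm1(gam * t)
    if params.family is ParametricFamily.lognormal:
        z = gam * (math.log(lam) + logt)
        return -0.5 * z * z - 0.5 * math.log(2 * math.pi) + math.log(gam) - logt
    if params.family is ParametricFamily.loglogistic:
        p = params._ll_shape()
        u = p * (math.log(lam) + logt)
        # log f = log p + p log(λ) + (p-1) log t - 2 log(1+(λt)^p)
        return math.log(p) + u - logt - 2.0 * np.logaddexp(0.0, u)
    raise ValueError(params.family)  # pragma: no cover


def _log_sf(params: SurvivalParams, t: np.ndarray) -> np.ndarray:
    """log S(t), numerically stable."""
    lam, gam = params.lambda_, params.gamma_
    if params.family is ParametricFamily.exponential:
        return -lam * t
    if params.family is ParametricFamily.weibull:
        return -((lam * t) ** gam)
    if params.family is ParametricFamily.gompertz:
        return -(lam / gam) * np.expm1(gam * t)
    if params.family is ParametricFamily.lognormal:
        z = np.where(t > 0, gam * np.log(np.maximum(lam * t, 1e-300)), -np.inf)
        return special.log_ndtr(-z)
    if params.family is ParametricFamily.loglogistic:
        p = params._ll_shape()
        u = np.where(t > 0, p * np.log(np.maximum(lam * t, 1e-300)), -np.inf)
        return -np.logaddexp(0.0, u)
    raise ValueError(params.family)  # pragma: no cover


def median_survival(params: SurvivalParams) -> float:
    """Time t* (months) with S(t*) = 1/2, by closed form."""
    lam, gam = params.lambda_, params.gamma_
    ln2 = math.log(2.0)
    if params.family is ParametricFamily.exponential:
        return ln2 / lam
    if params.family is ParametricFamily.weibull:
        return ln2 ** (1.0 / gam) / lam
    if params.family is ParametricFamily.gompertz:
        return math.log1p(gam * ln2 / lam) / gam
    # Both the lognormal (as parameterized here) and the loglogistic have
    # median exactly 1/λ, whichever γ convention is active.
    return 1.0 / lam


def median_survival_numeric(params: SurvivalParams, tol: float = 1e-8) -> float:
    """Median by bracketed root-finding on S(t) - 1/2 (cross-check path)."""
    hi = 1.0
    while survival_at(params, hi) > 0.5:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("failed to bracket the median")
    return optimize.brentq(lambda t: survival_at(params, t) - 0.5, 0.0, hi, xtol=tol, rtol=tol)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family to right-censored data."""

    params: SurvivalParams
    loglik: float
    aic: float
    n: int
    n_events: int


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k − 2·loglik."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def _neg_loglik(theta: np.ndarray, family: ParametricFamily, ll_convention: str,
                t_ev: np.ndarray, t_cen: np.ndarray) -> float:
    lam = math.exp(theta[0])
    gam = math.exp(theta[1]) if len(theta) > 1 else 1.0
    if lam > 1e8 or gam > 1e4 or lam < 1e-10 or gam < 1e-4:
        return 1e12
    p = SurvivalParams(family, lam, gam, ll_convention)
    ll = 0.0
    if t_ev.size:
        ll += float(np.sum(_log_pdf(p, t_ev)))
    if t_cen.size:
        ll += float(np.sum(_log_sf(p, t_cen)))
    if not math.isfinite(ll):
        return 1e12
    return -ll


def fit_aft(ipd: Sequence[IPDRecord], family: ParametricFamily,
            ll_convention: str = LL_AFT_SCALE) -> FitResult:
    """Fit one AFT family to right-censored data by maximum likelihood.

    Deterministic: the optimizer is restarted from a fixed 3×3 grid of
    (λ, γ) seeds around a moment-based initial guess and the best optimum
    is kept.  Event times of exactly zero are nudged to 1e-6 months.
    """
    family = ParametricFamily(family)
    t, e = _as_arrays(ipd)
    if t.size < 2:
        raise DegenerateDataError("need at least 2 records")
    n_events = int(e.sum())
    if n_events == 0:
        raise DegenerateDataError("no events: parameters are not identifiable")
    t_ev = np.maximum(t[e], 1e-6)
    t_cen = t[~e]

    # Moment-based anchor: exponential MLE rate = events / total exposure.
    lam0 = n_events / max(float(t.sum()), 1e-12)

    if family is ParametricFamily.exponential:
        lam_hat = lam0  # closed form
        params = SurvivalParams(family, lam_hat)
        ll = float(np.sum(_log_pdf(params, t_ev))) + float(np.sum(_log_sf(params, t_cen)))
        return FitResult(params, ll, aic(ll, 1), int(t.size), n_events)

    best = None
    for fl in (0.5, 1.0, 2.0):
        for fg in (0.5, 1.0, 2.0):
            x0 = np.array([math.log(lam0 * fl), math.log(fg)])
            res = optimize.minimize(
                _neg_loglik, x0, args=(family, ll_convention, t_ev, t_cen),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e11:
        raise ConvergenceError(f"{family.value}: no finite optimum found from the start grid")
    lam_hat, gam_hat = math.exp(best.x[0]), math.exp(best.x[1])
    params = SurvivalParams(family, lam_hat, gam_hat, ll_convention)
    ll = -float(best.fun)
    return FitResult(params, ll, aic(ll, 2), int(t.size), n_events)


@dataclass(frozen=True)
class FamilyComparison:
    """All-family fit comparison; failures are recorded, not raised."""

    results: tuple[FitResult, ...]        # sorted ascending by AIC
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> FitResult:
        return self.results[0]


def compare_families(ipd: Sequence[IPDRecord],
                     ll_convention: str = LL_AFT_SCALE) -> FamilyComparison:
    """Fit all five families and rank by AIC (ties broken by enum order)."""
    ipd = list(ipd)
    if not ipd:
        raise DegenerateDataError("empty IPD")
    results: list[tuple[float, int, FitResult]] = []
    failures: dict[str, str] = {}
    for order, fam in enumerate(ParametricFamily):
        try:
            fr = fit_aft(ipd, fam, ll_convention)
        except (DegenerateDataError, ConvergenceError, ValueError) as exc:
            failures[fam.value] = str(exc)
            continue
        results.append((fr.aic, order, fr))
    if not results:
        raise ConvergenceError(f"every family failed to fit: {failures}")
    results.sort(key=lambda r: (r[0], r[1]))
    return FamilyComparison(tuple(r[2] for r in results), failures)
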