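"""Synthetic right-censored survival data and Kaplan-Meier summaries.

Stands in for trial-level data that is not publicly available: event times
are drawn by inverse-CDF sampling from any of the five parametric families,
censoring is the minimum of an administrative cutoff and exponential
dropout, and digitized-curve inputs (KM coordinates plus a number-at-risk
table) are produced exactly as a figure digitization would supply them.

Default cohort sizes (300 active / 150 control) are synthetic stand-ins of
roughly trial-like magnitude, not the source trial's actual arm sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import special

from .survival import IPDRecord, ParametricFamily, SurvivalParams

__all__ = ["SimSpec", "simulate_ipd", "km_from_ipd", "KMCurve"]


@dataclass(frozen=True)
class KMCurve:
    """Digitized KM curve: (time, survival) coordinates plus risk table."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    risk_times: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    total_events: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        s = np.asarray(self.survival, float)
        if t.size < 1 or t.size != s.size:
            raise ValueError("times and survival must be equal-length, non-empty")
        if t[0] != 0.0 or s[0] != 1.0:
            raise ValueError("curve must start at (0, 1.0)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        rt = np.asarray(self.risk_times, float)
        rn = np.asarray(self.n_at_risk, float)
        if rt.size < 2 or rt.size != rn.size:
            raise ValueError("risk table needs >= 2 rows of matching length")
        if np.any(np.diff(rt) <= 0) or np.any(np.diff(rn) > 0):
            raise ValueError("risk times must increase and n at risk must not")


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one simulated right-censored cohort."""

    family: ParametricFamily
    lambda_: float
    gamma_: float = 1.0
    n: int = 300
    admin_censor_months: float = 60.0
    dropout_rate: float = 0.0   # per-month exponential dropout hazard
    seed: int = 0
    ll_convention: str = "aft_scale"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.admin_censor_months <= 0:
            raise ValueError("administrative censor time must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be >= 0")

    @property
    def params(self) -> SurvivalParams:
        return SurvivalParams(self.family, self.lambda_, self.gamma_, self.ll_convention)


def _inverse_survival(params: SurvivalParams, u: np.ndarray) -> np.ndarray:
    """Solve S(T) = u for T (u uniform on (0,1)); exact per family."""
    lam, gam = params.lambda_, params.gamma_
    fam = params.family
    if fam is ParametricFamily.exponential:
        return -np.log(u) / lam
    if fam is ParametricFamily.weibull:
        return (-np.log(u)) ** (1.0 / gam) / lam
    if fam is ParametricFamily.gompertz:
        return np.log1p(-(gam / lam) * np.log(u)) / gam
    if fam is ParametricFamily.lognormal:
        z = special.ndtri(1.0 - u)          # Φ(z) = 1-u  ⇒  S = u
        return np.exp(z / gam) / lam
    if fam is ParametricFamily.loglogistic:
        p = params._ll_shape()
        return ((1.0 - u) / u) ** (1.0 / p) / lam
    raise ValueError(fam)  # pragma: no cover


def simulate_ipd(spec: SimSpec) -> list[IPDRecord]:
    """Draw a right-censored cohort; reproducible for a given seed."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    event_t = _inverse_survival(spec.params, u)
    censor_t = np.full(spec.n, float(spec.admin_censor_months))
    if spec.dropout_rate > 0:
        censor_t = np.minimum(censor_t, rng.exponential(1.0 / spec.dropout_rate, size=spec.n))
    obs = np.minimum(event_t, censor_t)
    ev = event_t <= censor_t
    return [IPDRecord(float(t), bool(e)) for t, e in zip(obs, ev)]


def km_from_ipd(ipd: Sequence[IPDRecord], risk_times: Sequence[float]) -> KMCurve:
    """Product-limit estimate at event times plus a number-at-risk table."""
    ipd = list(ipd)
    if not ipd:
        raise ValueError("empty IPD")
    t = np.asarray([r.time for r in ipd], float)
    e = np.asarray([r.event for r in ipd], bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    if times[0] != 0.0:
        times = np.insert(times, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
    # keep only distinct drop points (digitizers record steps, not flats)
    keep = np.concatenate([[True], np.diff(surv) < 0])
    times, surv = times[keep], surv[keep]
    rt = [float(x) for x in risk_times]
    n_at_risk = [int(np.sum(t >= x)) for x in rt]
    return KMCurve(tuple(times), tuple(surv), tuple(rt), tuple(n_at_risk),
                   total_events=int(e.sum()))
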