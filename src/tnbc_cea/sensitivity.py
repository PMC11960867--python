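"""One-way (tornado) and probabilistic sensitivity analysis with CEAC.

Survival parameters stay fixed at their base values throughout: the
published parameter table assigns them no range or distribution.  Economic
inputs are varied one at a time over their printed ranges (tornado) or
drawn jointly from method-of-moments distributions (PSA), treating each
printed range as a 95% interval, i.e. sd = (high − low)/3.92.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .economics import EconomicInputs, PARAMETER_RANGES, accrue
from .markov import CohortTrace, ModelConfig
from .results import icer

__all__ = ["OWSAEntry", "build_distribution", "one_way", "tornado",
           "PSAResult", "psa", "default_wtp_grid"]


@dataclass(frozen=True)
class OWSAEntry:
    name: str
    low_value: float
    high_value: float
    low_icer: float
    high_icer: float

    @property
    def spread(self) -> float:
        return abs(self.high_icer - self.low_icer)


def _rerun(inputs: EconomicInputs, config: ModelConfig,
           traces: dict[str, CohortTrace]):
    return icer(accrue(traces["combo"], "combo", inputs, config),
                accrue(traces["placebo"], "placebo", inputs, config),
                config)


def one_way(param_name: str, inputs: EconomicInputs, config: ModelConfig,
            traces: dict[str, CohortTrace]) -> OWSAEntry:
    """Rerun the base case at the parameter's low and high bounds."""
    if param_name not in PARAMETER_RANGES:
        raise KeyError(f"unknown parameter {param_name!r}")
    low, high, _ = PARAMETER_RANGES[param_name]
    r_low = _rerun(inputs.with_value(param_name, low), config, traces)
    r_high = _rerun(inputs.with_value(param_name, high), config, traces)
    return OWSAEntry(param_name, low, high, r_low.icer, r_high.icer)


def tornado(inputs: EconomicInputs, config: ModelConfig,
            traces: dict[str, CohortTrace]) -> pd.DataFrame:
    """One-way results for every ranged parameter, sorted by ICER spread."""
    entries = [one_way(name, inputs, config, traces) for name in PARAMETER_RANGES]
    df = pd.DataFrame(
        [(e.name, e.low_icer, e.high_icer, e.spread) for e in entries],
        columns=["parameter", "low_icer", "high_icer", "spread"],
    )
    return df.sort_values("spread", ascending=False, ignore_index=True)


def build_distribution(base: float, low: float, high: float, family: str):
    """Method-of-moments sampler with mean=base, sd=(high−low)/3.92.

    gamma: shape = mean²/sd², scale = sd²/mean;
    beta:  α = mean·ν, β = (1−mean)·ν with ν = mean(1−mean)/sd² − 1;
    normal: (mean, sd).
    """
    if not (low <= base <= high):
        raise ValueError(f"need low <= base <= high, got {low}, {base}, {high}")
    sd = (high - low) / 3.92
    if sd <= 0:
        raise ValueError("degenerate range: sd must be positive")
    if family == "gamma":
        if base <= 0:
            raise ValueError("gamma requires a positive mean")
        return stats.gamma(a=base**2 / sd**2, scale=sd**2 / base)
    if family == "beta":
        if not 0 < base < 1:
            raise ValueError("beta requires mean in (0, 1)")
        nu = base * (1 - base) / sd**2 - 1
        if nu <= 0:
            raise ValueError("range too wide for a beta with this mean")
        return stats.beta(a=base * nu, b=(1 - base) * nu)
    if family == "normal":
        return stats.norm(loc=base, scale=sd)
    raise ValueError(f"unknown distribution family {family!r}")


def default_wtp_grid() -> np.ndarray:
    """$0 to $1,200,000 in $10,000 steps (includes the $100,000 threshold)."""
    return np.arange(0.0, 1_200_000.0 + 1, 10_000.0)


@dataclass(frozen=True)
class PSAResult:
    draws: pd.DataFrame      # one row per successful iteration
    ceac: pd.DataFrame       # columns: wtp, prob_combo_ce
    n_failed: int

    def ceac_at(self, wtp: float) -> float:
        idx = (self.ceac["wtp"] - wtp).abs().idxmin()
        return float(self.ceac.loc[idx, "prob_combo_ce"])


def psa(inputs: EconomicInputs, config: ModelConfig,
        traces: dict[str, CohortTrace], n_iter: int = 2_000,
        seed: int = 0, wtp_grid: np.ndarray | None = None) -> PSAResult:
    """Joint Monte-Carlo resampling of every ranged economic input.

    Reproducible for a given seed: one substream per parameter, in sorted
    parameter order.  Draws for which the model fails (e.g. an out-of-range
    sampled value) are dropped and counted.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(PARAMETER_RANGES)
    samples = {}
    for name in names:
        low, high, fam = PARAMETER_RANGES[name]
        dist = build_distribution(getattr(inputs, name), low, high, fam)
        samples[name] = dist.rvs(size=n_iter, random_state=rng)

    rows, n_failed = [], 0
    for i in range(n_iter):
        try:
            draw = inputs
            for name in names:
                draw = draw.with_value(name, float(samples[name][i]))
            res = _rerun(draw, config, traces)
        except (ValueError, KeyError):
            n_failed += 1
            continue
        rows.append((res.combo.total_cost, res.combo.qaly,
                     res.placebo.total_cost, res.placebo.qaly,
                     res.delta_cost, res.delta_qaly))
    draws = pd.DataFrame(rows, columns=["cost_combo", "qaly_combo",
                                        "cost_placebo", "qaly_placebo",
                                        "delta_cost", "delta_qaly"])
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    prob = [(w * dq - dc >= 0).mean() if len(dq) else np.nan for w in grid]
    ceac = pd.DataFrame({"wtp": grid, "prob_combo_ce": prob})
    return PSAResult(draws, ceac, n_failed)
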