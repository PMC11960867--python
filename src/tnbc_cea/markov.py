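"""Three-state cohort engine: PFS, progressed disease (PD), death.

State occupancy is evaluated by partitioned survival: the PFS curve gives
progression-free occupancy, the OS curve gives the alive fraction, and PD
is their difference.  A tunnel bookkeeping of time-since-progression is
carried along so post-progression costs can be capped at a fixed duration.
The cycle grid is 21 days; the terminal cycle is truncated so the horizon
ends exactly at ``horizon_years``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .survival import SurvivalParams, survival_at

__all__ = ["ModelConfig", "CohortTrace", "transition_probability", "run_trace",
           "ModelInconsistencyError"]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

SUBSEQUENT_ALL_PD = "all_pd"
SUBSEQUENT_CAPPED = "capped_35w"
TERMINAL_INCIDENT = "incident"
TERMINAL_COHORT = "cohort"


class ModelInconsistencyError(ValueError):
    """PFS curve exceeds OS curve beyond tolerance (curves cross)."""


@dataclass(frozen=True)
class ModelConfig:
    """Structural settings and accrual conventions of the cohort model.

    The defaults reproduce the shipped base case: 21-day cycles over a
    5-year horizon (87 cycles), 5%/year discounting, treatment capped at
    2 years, $100,000/QALY willingness-to-pay.  Accrual conventions that
    the underlying publication leaves open are exposed as flags:

    * ``vial_rounding`` — round each nab-paclitaxel administration up to
      whole 100 mg vials (wastage included).
    * ``subsequent_therapy_mode`` — ``"all_pd"`` accrues the per-cycle
      subsequent-therapy cost on all PD occupancy; ``"capped_35w"`` caps it
      at ``subsequent_therapy_weeks`` after progression via the tunnel.
    * ``terminal_cost_mode`` — ``"incident"`` attaches terminal care to
      deaths in the cycle they occur (discounted); ``"cohort"`` charges it
      once per modelled patient, undiscounted.
    * ``half_cycle_correction`` — average state membership across cycle
      boundaries instead of counting it at cycle start.
    """

    cycle_days: float = 21.0
    horizon_years: float = 5.0
    discount_rate_annual: float = 0.05
    wtp_per_qaly: float = 100_000.0
    treatment_cap_years: float = 2.0
    subsequent_therapy_weeks: float = 35.0
    half_cycle_correction: bool = False
    vial_rounding: bool = True
    subsequent_therapy_mode: str = SUBSEQUENT_ALL_PD
    terminal_cost_mode: str = TERMINAL_INCIDENT
    ct_every_n_cycles: int = 3

    def __post_init__(self) -> None:
        for name in ("cycle_days", "horizon_years", "treatment_cap_years",
                     "subsequent_therapy_weeks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.discount_rate_annual < 0:
            raise ValueError("discount rate must be >= 0")
        if self.subsequent_therapy_mode not in (SUBSEQUENT_ALL_PD, SUBSEQUENT_CAPPED):
            raise ValueError(f"unknown subsequent_therapy_mode {self.subsequent_therapy_mode!r}")
        if self.terminal_cost_mode not in (TERMINAL_INCIDENT, TERMINAL_COHORT):
            raise ValueError(f"unknown terminal_cost_mode {self.terminal_cost_mode!r}")

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_days)

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    def cycle_start_years(self) -> np.ndarray:
        """Start time (years) of each of the n_cycles cycles."""
        return np.arange(self.n_cycles) * self.cycle_years

    def cycle_widths_years(self) -> np.ndarray:
        """Cycle lengths in years; the final cycle is truncated to the horizon."""
        edges = np.minimum(np.arange(self.n_cycles + 1) * self.cycle_years,
                           self.horizon_years)
        return np.diff(edges)

    def boundary_months(self) -> np.ndarray:
        """Cycle-boundary times in months, truncated at the horizon."""
        return np.minimum(np.arange(self.n_cycles + 1) * self.cycle_months,
                          self.horizon_years * 12.0)

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of the cohort (proportions of 1).

    Arrays are indexed by cycle boundary 0..n_cycles; ``new_progressions``
    and ``new_deaths`` hold the incident flow during cycle t-1 → t (entry 0
    is zero).  ``pd_tunnel[t, j]`` is PD occupancy at boundary t among
    patients who progressed j cycles earlier; rows sum to ``pd_occ``.
    """

    pfs_occ: np.ndarray
    pd_occ: np.ndarray
    dead_occ: np.ndarray
    new_progressions: np.ndarray
    new_deaths: np.ndarray
    pd_tunnel: np.ndarray
    config: ModelConfig = field(repr=False, default=None)

    @property
    def alive(self) -> np.ndarray:
        return self.pfs_occ + self.pd_occ

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "cycle": np.arange(self.pfs_occ.size),
            "pfs": self.pfs_occ, "pd": self.pd_occ, "dead": self.dead_occ,
            "new_prog": self.new_progressions, "new_death": self.new_deaths,
        })


def transition_probability(params: SurvivalParams, cycle_index: int,
                           config: ModelConfig) -> float:
    """Per-cycle exit probability 1 − S((t+1)u)/S(tu), u = cycle months."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    u = config.cycle_months
    s0 = survival_at(params, cycle_index * u)
    if s0 <= 0.0:
        return 1.0
    s1 = survival_at(params, (cycle_index + 1) * u)
    return float(np.clip(1.0 - s1 / s0, 0.0, 1.0))


def run_trace(pfs: SurvivalParams, os: SurvivalParams,
              config: ModelConfig | None = None,
              crossing_tol: float = 0.02) -> CohortTrace:
    """Build the cohort trace from an arm's PFS and OS curves.

    Raises ``ModelInconsistencyError`` (naming the first offending cycle)
    if S_pfs exceeds S_os by more than ``crossing_tol`` anywhere on the
    cycle grid; smaller crossings are clipped.
    """
    config = config or ModelConfig()
    n = config.n_cycles
    t_m = config.boundary_months()
    s_pfs = np.asarray(survival_at(pfs, t_m), float)
    s_os = np.asarray(survival_at(os, t_m), float)
    excess = s_pfs - s_os
    if np.any(excess > crossing_tol):
        cyc = int(np.argmax(excess > crossing_tol))
        raise ModelInconsistencyError(
            f"PFS exceeds OS by {excess[cyc]:.4f} at cycle {cyc} "
            f"(tolerance {crossing_tol})"
        )
    pfs_occ = np.minimum(s_pfs, s_os)
    dead_occ = 1.0 - s_os
    pd_occ = np.maximum(s_os - s_pfs, 0.0)

    new_deaths = np.zeros(n + 1)
    new_deaths[1:] = np.diff(dead_occ)
    # deaths apportioned to PFS in proportion to previous-boundary occupancy
    alive_prev = np.maximum(pfs_occ[:-1] + pd_occ[:-1], 1e-300)
    pfs_share = pfs_occ[:-1] / alive_prev
    new_prog = np.zeros(n + 1)
    new_prog[1:] = np.maximum(-np.diff(pfs_occ) - new_deaths[1:] * pfs_share, 0.0)

    # tunnel: entrants at position 0, proportional attrition, then ageing
    tunnel = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        aged = np.roll(tunnel[i - 1], 1)
        aged[0] = 0.0
        prev_total = aged.sum()
        target_old = max(pd_occ[i] - new_prog[i], 0.0)
        if prev_total > 1e-300:
            aged *= target_old / prev_total
        row = aged
        row[0] = min(new_prog[i], pd_occ[i])
        # numerical guard: rescale so the row sums exactly to pd occupancy
        s = row.sum()
        if s > 1e-300:
            row *= pd_occ[i] / s
        tunnel[i] = row

    return CohortTrace(pfs_occ, pd_occ, dead_occ, new_prog, new_deaths,
                       tunnel, config)
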