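"""Cost and QALY accrual over a cohort trace.

All prices are 2024 US dollars.  Drug acquisition accrues on
progression-free occupancy while on treatment (capped at 2 years);
monitoring (labs every cycle, CT plus tumor imaging every third cycle)
accrues on the alive states; subsequent therapy accrues on PD occupancy
(optionally capped at 35 weeks after progression via the tunnel);
terminal care attaches to deaths; grade >= 3 adverse-event costs and
disutilities are front-loaded into the first cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from .markov import (CohortTrace, ModelConfig, SUBSEQUENT_CAPPED,
                     TERMINAL_COHORT)

__all__ = ["EconomicInputs", "Accrual", "PARAMETER_RANGES", "drug_cost_cycle",
           "subsequent_cycle_cost", "ae_burden_first_cycle", "discount_factor",
           "accrue", "ARMS"]

ARMS = ("combo", "placebo")

NABPAC_DOSE_MG_PER_M2 = 125.0
NABPAC_ADMIN_PER_CYCLE = 2          # days 1 and 8 of each 21-day cycle
# subsequent therapy modelled as carboplatin + gemcitabine (GP doublet):
# carboplatin AUC 2 (Calvert, GFR 90 -> 230 mg) and gemcitabine
# 1000 mg/m2, each on days 1 and 8.  Unit prices and BSA feed the printed
# per-cycle total; everything above drug acquisition is a fixed overhead.
CARBO_MG_PER_ADMIN = 230.0
GEM_MG_PER_M2 = 1000.0
_REF_CARBO_PRICE = 0.06
_REF_GEM_PRICE = 0.02
_REF_BSA = 1.84


@dataclass(frozen=True)
class EconomicInputs:
    """Unit costs, utilities and adverse-event inputs (base-case defaults)."""

    cost_toripalimab_cycle: float = 8_892.03   # per 240 mg dose, one per cycle
    cost_nabpac_100mg: float = 1_447.14        # per 100 mg vial
    cost_subsequent_cycle: float = 6_533.66    # per 21-day post-progression cycle
    cost_lab: float = 16.36
    cost_ct: float = 152.62
    cost_imaging: float = 105.0
    cost_terminal: float = 85_904.0            # per death
    cost_carboplatin_mg: float = 0.06
    cost_gemcitabine_mg: float = 0.02
    bsa: float = 1.84                          # body surface area, m^2
    cost_leukopenia: float = 57.21
    cost_neutropenia: float = 24_376.0
    u_pfs: float = 0.76
    u_pd: float = 0.55
    disutil_leukopenia: float = 0.09
    disutil_neutropenia: float = 0.10
    ae_leukopenia_combo: float = 0.25
    ae_neutropenia_combo: float = 0.26
    ae_leukopenia_placebo: float = 0.23
    ae_neutropenia_placebo: float = 0.28

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        for name in ("u_pfs", "u_pd", "disutil_leukopenia", "disutil_neutropenia",
                     "ae_leukopenia_combo", "ae_neutropenia_combo",
                     "ae_leukopenia_placebo", "ae_neutropenia_placebo"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def with_value(self, name: str, value: float) -> "EconomicInputs":
        if name not in {f.name for f in fields(self)}:
            raise KeyError(f"unknown parameter {name!r}")
        return replace(self, **{name: value})


# (low, high, distribution family) for every varied input; ranges are the
# published ones (mostly +/- 25%, a few asymmetric).
PARAMETER_RANGES: dict[str, tuple[float, float, str]] = {
    "cost_toripalimab_cycle": (7_113.62, 10_670.44, "gamma"),
    "cost_nabpac_100mg": (1_157.71, 1_736.57, "gamma"),
    "cost_subsequent_cycle": (5_226.93, 7_840.40, "gamma"),
    "cost_lab": (13.09, 19.63, "gamma"),
    "cost_ct": (122.09, 183.14, "gamma"),
    "cost_imaging": (84.0, 126.0, "gamma"),
    "cost_terminal": (68_723.0, 103_085.0, "gamma"),
    "cost_carboplatin_mg": (0.04, 0.07, "gamma"),
    "cost_gemcitabine_mg": (0.02, 0.03, "gamma"),
    "bsa": (1.78, 1.90, "normal"),
    "cost_leukopenia": (45.76, 68.65, "gamma"),
    "cost_neutropenia": (12_188.0, 49_913.0, "gamma"),
    "u_pfs": (0.61, 0.91, "beta"),
    "u_pd": (0.36, 0.55, "beta"),
    "disutil_leukopenia": (0.07, 0.10, "beta"),
    "disutil_neutropenia": (0.09, 0.11, "beta"),
    "ae_leukopenia_combo": (0.20, 0.30, "beta"),
    "ae_neutropenia_combo": (0.21, 0.31, "beta"),
    "ae_leukopenia_placebo": (0.18, 0.28, "beta"),
    "ae_neutropenia_placebo": (0.22, 0.34, "beta"),
}


def _nabpac_cost_cycle(inputs: EconomicInputs, config: ModelConfig) -> float:
    dose = NABPAC_DOSE_MG_PER_M2 * inputs.bsa
    vials = math.ceil(dose / 100.0) if config.vial_rounding else dose / 100.0
    return vials * inputs.cost_nabpac_100mg * NABPAC_ADMIN_PER_CYCLE


def drug_cost_cycle(arm: str, cycle_index: int, inputs: EconomicInputs,
                    config: ModelConfig) -> float:
    """Acquisition cost charged per patient-in-PFS for one cycle."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if cycle_index < 0 or cycle_index >= config.n_cycles:
        raise ValueError("cycle outside horizon")
    if cycle_index * config.cycle_years >= config.treatment_cap_years:
        return 0.0
    cost = _nabpac_cost_cycle(inputs, config)
    if arm == "combo":
        cost += inputs.cost_toripalimab_cycle
    return cost


def subsequent_cycle_cost(inputs: EconomicInputs) -> float:
    """Post-progression per-cycle cost.

    The printed per-cycle total corresponds to the GP doublet at reference
    unit prices; moving the carboplatin/gemcitabine prices or the BSA
    shifts only the drug-acquisition share of that total.
    """
    def drug_part(carbo: float, gem: float, bsa: float) -> float:
        return (CARBO_MG_PER_ADMIN * 2 * carbo
                + GEM_MG_PER_M2 * bsa * 2 * gem)

    return (inputs.cost_subsequent_cycle
            - drug_part(_REF_CARBO_PRICE, _REF_GEM_PRICE, _REF_BSA)
            + drug_part(inputs.cost_carboplatin_mg, inputs.cost_gemcitabine_mg,
                        inputs.bsa))


def ae_burden_first_cycle(arm: str, inputs: EconomicInputs,
                          config: ModelConfig) -> tuple[float, float]:
    """(cost, QALY decrement) of grade >= 3 AEs, charged once at cycle 0."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    leu = getattr(inputs, f"ae_leukopenia_{arm}")
    neu = getattr(inputs, f"ae_neutropenia_{arm}")
    cost = leu * inputs.cost_leukopenia + neu * inputs.cost_neutropenia
    decrement = (leu * inputs.disutil_leukopenia
                 + neu * inputs.disutil_neutropenia) * config.cycle_years
    return cost, decrement


def discount_factor(cycle_index: int, config: ModelConfig) -> float:
    """(1+r)^(−t) with t the cycle-start time in years."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    t = cycle_index * config.cycle_years
    return (1.0 + config.discount_rate_annual) ** (-t)


@dataclass(frozen=True)
class Accrual:
    """Discounted per-arm totals with a cost breakdown."""

    arm: str
    total_cost: float
    ly: float
    qaly: float
    breakdown: dict


def accrue(trace: CohortTrace, arm: str, inputs: EconomicInputs,
           config: ModelConfig) -> Accrual:
    """Accumulate discounted costs, life-years and QALYs over the trace."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    n = config.n_cycles
    if trace.pfs_occ.size != n + 1:
        raise ValueError("trace and config disagree on the cycle count")

    if config.half_cycle_correction:
        P = 0.5 * (trace.pfs_occ[:-1] + trace.pfs_occ[1:])
        D = 0.5 * (trace.pd_occ[:-1] + trace.pd_occ[1:])
    else:
        P = trace.pfs_occ[:-1]
        D = trace.pd_occ[:-1]
    A = P + D
    disc = (1.0 + config.discount_rate_annual) ** (-config.cycle_start_years())
    w_years = config.cycle_widths_years()

    # drug acquisition: constant while on treatment, zero after the cap
    on_trt = config.cycle_start_years() < config.treatment_cap_years
    c_drug = drug_cost_cycle(arm, 0, inputs, config) * float(np.sum(P * on_trt * disc))

    # monitoring
    mon = np.full(n, inputs.cost_lab)
    mon[np.arange(n) % config.ct_every_n_cycles == 0] += inputs.cost_ct + inputs.cost_imaging
    c_mon = float(np.sum(mon * A * disc))

    # subsequent therapy
    sub_c = subsequent_cycle_cost(inputs)
    if config.subsequent_therapy_mode == SUBSEQUENT_CAPPED:
        cap_cycles = config.subsequent_therapy_weeks * 7.0 / config.cycle_days
        ages = np.arange(trace.pd_tunnel.shape[1])
        wts = np.clip(cap_cycles - ages, 0.0, 1.0)
        eligible = trace.pd_tunnel[:-1] @ wts
        c_sub = sub_c * float(np.sum(eligible * disc))
    else:
        c_sub = sub_c * float(np.sum(D * disc))

    # terminal care
    if config.terminal_cost_mode == TERMINAL_COHORT:
        c_term = inputs.cost_terminal
    else:
        c_term = inputs.cost_terminal * float(np.sum(trace.new_deaths[1:] * disc))

    ae_cost, ae_dec = ae_burden_first_cycle(arm, inputs, config)

    ly = float(np.sum(A * w_years * disc))
    qaly = float(np.sum((inputs.u_pfs * P + inputs.u_pd * D) * w_years * disc)) - ae_dec
    total = c_drug + c_mon + c_sub + c_term + ae_cost
    return Accrual(arm, total, ly, qaly, {
        "drug": c_drug, "monitoring": c_mon, "subsequent": c_sub,
        "terminal": c_term, "adverse_events": ae_cost,
    })
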