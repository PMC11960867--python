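"""Incremental cost-effectiveness results for the two-strategy comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .economics import Accrual
from .markov import ModelConfig

__all__ = ["CEAResult", "icer"]


@dataclass(frozen=True)
class CEAResult:
    """Per-arm totals, incremental results and the WTP verdict.

    ``status`` is ``"icer"`` when the ratio is meaningful, ``"dominant"``
    (cheaper and more effective — no ratio), ``"dominated"`` (dearer and
    less effective) or ``"undefined"`` (effect difference below 1e-12).
    All differences are computed on unrounded internals.
    """

    combo: Accrual
    placebo: Accrual
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer: float            # NaN unless status == "icer"
    status: str
    wtp: float
    cost_effective: bool   # verdict for the combination at the WTP threshold

    def summary_lines(self) -> list[str]:
        rows = [
            f"{'strategy':28s} {'cost ($)':>14s} {'LY':>7s} {'QALY':>7s}",
            f"{'toripalimab + nab-paclitaxel':28s} {self.combo.total_cost:>14,.2f} "
            f"{self.combo.ly:>7.2f} {self.combo.qaly:>7.2f}",
            f"{'nab-paclitaxel alone':28s} {self.placebo.total_cost:>14,.2f} "
            f"{self.placebo.ly:>7.2f} {self.placebo.qaly:>7.2f}",
            f"incremental cost  : ${self.delta_cost:,.2f}",
            f"incremental QALYs : {self.delta_qaly:.4f}",
        ]
        if self.status == "icer":
            rows.append(f"ICER              : ${self.icer:,.2f} per QALY")
        else:
            rows.append(f"ICER              : {self.status}")
        verdict = "IS" if self.cost_effective else "is NOT"
        rows.append(f"At a WTP of ${self.wtp:,.0f}/QALY the combination "
                    f"{verdict} cost-effective.")
        return rows


def icer(combo: Accrual, placebo: Accrual, config: ModelConfig | None = None) -> CEAResult:
    """Incremental comparison of the combination arm against chemotherapy alone."""
    config = config or ModelConfig()
    d_cost = combo.total_cost - placebo.total_cost
    d_ly = combo.ly - placebo.ly
    d_q = combo.qaly - placebo.qaly
    if abs(d_q) < 1e-12:
        status, ratio = "undefined", math.nan
        ce = d_cost < 0
    elif d_cost < 0 and d_q > 0:
        status, ratio = "dominant", math.nan
        ce = True
    elif d_cost > 0 and d_q < 0:
        status, ratio = "dominated", math.nan
        ce = False
    else:
        status, ratio = "icer", d_cost / d_q
        ce = ratio <= config.wtp_per_qaly if d_q > 0 else ratio > config.wtp_per_qaly
    return CEAResult(combo, placebo, d_cost, d_ly, d_q, ratio, status,
                     config.wtp_per_qaly, ce)
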