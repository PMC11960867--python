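"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Implements the Guyot iterative algorithm: given digitized (time, survival)
coordinates and a number-at-risk table, per-interval event and censoring
counts are solved so that the reconstructed cohort's product-limit curve
reproduces the digitized one and its at-risk counts match the published
table.  Event times are placed at the digitized drop times; censoring
times are spread uniformly within each risk-table interval.
"""

from __future__ import annotations

import numpy as np

from .simulate import KMCurve
from .survival import IPDRecord

__all__ = ["reconstruct_ipd", "InfeasibleReconstructionError"]


class InfeasibleReconstructionError(ValueError):
    """Risk counts cannot be reconciled with the digitized survival drops."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def reconstruct_ipd(curve: KMCurve) -> list[IPDRecord]:
    """Reconstruct pseudo-IPD from a digitized KM curve and risk table.

    Returns one record per initially-at-risk subject.  If the curve carries
    ``total_events``, censoring in the final interval is calibrated so the
    reconstructed event count matches it; otherwise no censoring is assumed
    after the last risk-table time except administrative censoring of the
    survivors at end of follow-up.
    """
    t = np.asarray(curve.times, float)
    s = np.asarray(curve.survival, float)
    rt = np.asarray(curve.risk_times, float)
    nr = np.asarray(curve.n_at_risk, int)
    if rt.size < 2:
        raise ValueError("need at least 2 risk-table rows")
    t_max = max(t[-1], rt[-1])
    K = t.size

    # interval i spans [rt[i], rt[i+1]); the last interval runs to t_max.
    bounds = list(rt) + [np.nextafter(t_max, np.inf)]
    lower = [int(np.searchsorted(t, bounds[i], side="left")) for i in range(len(rt))]
    upper = [int(np.searchsorted(t, bounds[i + 1], side="left")) - 1 for i in range(len(rt))]

    d = np.zeros(K, int)              # events at coordinate k
    cen_times: list[float] = []
    n_cur = int(nr[0])
    km_prev = 1.0                     # KM value at the last processed event
    state0 = (n_cur, km_prev)

    def sweep(i: int, c_guess: int, n_start: int, km_start: float):
        """Walk interval i with c_guess censorings; return counts and end state."""
        lo_t, hi_t = bounds[i], bounds[i + 1]
        ct = [lo_t + (j + 1) * (min(hi_t, t_max) - lo_t) / (c_guess + 1) for j in range(c_guess)]
        n_k = n_start
        km = km_start
        dd = {}
        for k in range(lower[i], upper[i] + 1):
            if t[k] == 0.0:
                continue
            n_eff = n_k - sum(1 for x in ct if x < t[k])
            if n_eff <= 0:
                dd[k] = 0
                continue
            ev = _round_half_up(n_eff * (1.0 - s[k] / km)) if km > 0 else 0
            ev = int(np.clip(ev, 0, n_eff))
            dd[k] = ev
            if ev > 0:
                km = km * (1.0 - ev / n_eff)
            n_k -= ev
        n_end = n_k - c_guess
        return dd, ct, n_end, km

    for i in range(len(rt) - 1):
        n_start, km_start = state0
        target = int(nr[i + 1])
        c = max(n_start - target - 0, 0)  # initial guess ignoring events
        seen = set()
        while True:
            dd, ct, n_end, km_end = sweep(i, c, n_start, km_start)
            diff = n_end - target
            if diff == 0:
                break
            c_new = c + diff
            if c_new < 0:
                raise InfeasibleReconstructionError(
                    f"interval starting at t={rt[i]:g}: risk table implies "
                    f"negative censoring ({c_new})"
                )
            if c_new in seen:   # oscillation: accept the closer of the two
                break
            seen.add(c)
            c = c_new
        for k, v in dd.items():
            d[k] = v
        cen_times.extend(ct)
        state0 = (target, km_end)

    # final interval [rt[-1], t_max]
    i = len(rt) - 1
    n_start, km_start = state0
    if curve.total_events is not None:
        target_ev = int(curve.total_events) - int(d.sum())
        best = None
        for c in range(0, n_start + 1):
            dd, ct, n_end, _ = sweep(i, c, n_start, km_start)
            err = abs(sum(dd.values()) - target_ev)
            if best is None or err < best[0]:
                best = (err, dd, ct, n_end)
            if err == 0:
                break
        _, dd, ct, n_end = best
    else:
        dd, ct, n_end, _ = sweep(i, 0, n_start, km_start)
    for k, v in dd.items():
        d[k] = v
    cen_times.extend(ct)

    records = []
    for k in range(K):
        records.extend(IPDRecord(float(t[k]), True) for _ in range(d[k]))
    records.extend(IPDRecord(float(x), False) for x in cen_times)
    n_left = int(nr[0]) - len(records)
    if n_left < 0:
        raise InfeasibleReconstructionError(
            "reconstructed more subjects than initially at risk"
        )
    records.extend(IPDRecord(float(t_max), False) for _ in range(n_left))
    return sorted(records, key=lambda r: (r.time, not r.event))
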