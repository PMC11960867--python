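"""CSV interchange for IPD, digitized curves and fit tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .simulate import KMCurve
from .survival import FitResult, IPDRecord

__all__ = ["read_ipd_csv", "write_ipd_csv", "read_km_csv", "write_km_csv",
           "fit_results_frame"]


def write_ipd_csv(ipd: Sequence[IPDRecord], path) -> None:
    pd.DataFrame({"time_months": [r.time for r in ipd],
                  "event": [int(r.event) for r in ipd]}).to_csv(path, index=False)


def read_ipd_csv(path) -> list[IPDRecord]:
    df = pd.read_csv(path)
    missing = {"time_months", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"IPD CSV is missing columns: {sorted(missing)}")
    return [IPDRecord(float(t), bool(e))
            for t, e in zip(df["time_months"], df["event"])]


def write_km_csv(curve: KMCurve, points_path, risk_path) -> None:
    pd.DataFrame({"time_months": curve.times,
                  "survival": curve.survival}).to_csv(points_path, index=False)
    pd.DataFrame({"time_months": curve.risk_times,
                  "n_at_risk": curve.n_at_risk}).to_csv(risk_path, index=False)


def read_km_csv(points_path, risk_path, total_events: int | None = None) -> KMCurve:
    pts = pd.read_csv(points_path)
    risk = pd.read_csv(risk_path)
    return KMCurve(tuple(pts["time_months"].astype(float)),
                   tuple(pts["survival"].astype(float)),
                   tuple(risk["time_months"].astype(float)),
                   tuple(risk["n_at_risk"].astype(int)),
                   total_events=total_events)


def fit_results_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "family": r.params.family.value,
        "lambda": r.params.lambda_,
        "gamma": r.params.gamma_,
        "loglik": r.loglik,
        "aic": r.aic,
        "n": r.n,
        "n_events": r.n_events,
    } for r in results])
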