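"""Configuration loading, defaults, run manifest and report assembly.

A single JSON file with sections {model, survival, costs, utilities,
adverse_events, psa} configures a run; every field left out falls back to
the shipped base case, so an empty config reproduces it exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .economics import EconomicInputs, accrue
from .markov import ModelConfig, run_trace
from .results import CEAResult, icer
from .sensitivity import psa, tornado
from .survival import ParametricFamily, SurvivalParams

__all__ = ["RunSpec", "ConfigError", "default_curves", "load_config",
           "RunManifest", "run_report"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending field."""


#: Base-case loglogistic parameters (per month) for the four fitted curves.
BASE_CURVES = {
    "combo": {"pfs": (0.11338, 0.64072), "os": (0.03223, 0.60082)},
    "placebo": {"pfs": (0.14152, 0.53806), "os": (0.04349, 0.53309)},
}


def default_curves(ll_convention: str = "aft_scale") -> dict[str, dict[str, SurvivalParams]]:
    return {
        arm: {endpoint: SurvivalParams(ParametricFamily.loglogistic, lam, gam,
                                       ll_convention)
              for endpoint, (lam, gam) in curves.items()}
        for arm, curves in BASE_CURVES.items()
    }


@dataclass(frozen=True)
class RunSpec:
    """Fully-resolved inputs of one analysis run."""

    model: ModelConfig
    inputs: EconomicInputs
    curves: dict            # arm -> {"pfs": SurvivalParams, "os": SurvivalParams}
    psa_n_iter: int = 2_000
    psa_seed: int = 0

    def traces(self):
        return {arm: run_trace(c["pfs"], c["os"], self.model)
                for arm, c in self.curves.items()}

    def base_case(self) -> CEAResult:
        tr = self.traces()
        return icer(accrue(tr["combo"], "combo", self.inputs, self.model),
                    accrue(tr["placebo"], "placebo", self.inputs, self.model),
                    self.model)

    def canonical_dict(self) -> dict:
        return {
            "model": asdict(self.model),
            "survival": {arm: {ep: {"family": p.family.value, "lambda": p.lambda_,
                                    "gamma": p.gamma_, "ll_convention": p.ll_convention}
                               for ep, p in c.items()}
                         for arm, c in self.curves.items()},
            "economics": asdict(self.inputs),
            "psa": {"n_iter": self.psa_n_iter, "seed": self.psa_seed},
        }

    def digest(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _apply_section(cls, base_kwargs: dict, overrides: dict, section: str) -> dict:
    known = {f.name for f in fields(cls)}
    for key, val in overrides.items():
        if key not in known:
            raise ConfigError(f"{section}.{key}: unknown field")
        base_kwargs[key] = val
    return base_kwargs


def load_config(path=None) -> RunSpec:
    """Load a JSON config; omitted fields default to the shipped base case."""
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            raw = json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a JSON object")
    known_sections = {"model", "survival", "costs", "utilities",
                      "adverse_events", "psa"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")

    try:
        model = ModelConfig(**_apply_section(ModelConfig, {}, raw.get("model", {}),
                                             "model"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"model: {exc}") from exc

    econ_kwargs: dict = {}
    for section in ("costs", "utilities", "adverse_events"):
        _apply_section(EconomicInputs, econ_kwargs, raw.get(section, {}), section)
    try:
        inputs = EconomicInputs(**econ_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    surv = raw.get("survival", {})
    ll_conv = surv.get("ll_convention", "aft_scale")
    curves = default_curves(ll_conv)
    for arm, eps in surv.get("arms", {}).items():
        if arm not in curves:
            raise ConfigError(f"survival.arms.{arm}: unknown arm")
        for ep, spec in eps.items():
            if ep not in ("pfs", "os"):
                raise ConfigError(f"survival.arms.{arm}.{ep}: unknown endpoint")
            try:
                curves[arm][ep] = SurvivalParams(
                    ParametricFamily(spec.get("family", "loglogistic")),
                    float(spec["lambda"]), float(spec.get("gamma", 1.0)),
                    spec.get("ll_convention", ll_conv))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"survival.arms.{arm}.{ep}: {exc}") from exc

    psa_raw = raw.get("psa", {})
    n_iter = int(psa_raw.get("n_iter", 2_000))
    seed = int(psa_raw.get("seed", 0))
    if n_iter < 1:
        raise ConfigError("psa.n_iter must be >= 1")
    return RunSpec(model, inputs, curves, n_iter, seed)


@dataclass
class RunManifest:
    """Provenance of one report run: config digest, seed, outputs."""

    config_digest: str
    seed: int
    version: str
    timestamp: str
    accrual_flags: dict
    outputs: list

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def run_report(spec: RunSpec, out_dir, seed: int | None = None,
               n_iter: int | None = None) -> RunManifest:
    """Base case + tornado + PSA; writes CSVs, a text summary and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = spec.psa_seed if seed is None else seed
    n_iter = spec.psa_n_iter if n_iter is None else n_iter

    traces = spec.traces()
    base = icer(accrue(traces["combo"], "combo", spec.inputs, spec.model),
                accrue(traces["placebo"], "placebo", spec.inputs, spec.model),
                spec.model)
    base_df = pd.DataFrame([
        {"strategy": "toripalimab_plus_nab_paclitaxel",
         "total_cost": base.combo.total_cost, "ly": base.combo.ly,
         "qaly": base.combo.qaly, "icer": base.icer},
        {"strategy": "nab_paclitaxel_alone",
         "total_cost": base.placebo.total_cost, "ly": base.placebo.ly,
         "qaly": base.placebo.qaly, "icer": np.nan},
    ])
    base_df.to_csv(out / "basecase.csv", index=False)

    torn = tornado(spec.inputs, spec.model, traces)
    torn.to_csv(out / "tornado.csv", index=False)

    psa_res = psa(spec.inputs, spec.model, traces, n_iter=n_iter, seed=seed)
    psa_res.draws.to_csv(out / "psa_draws.csv", index=False)
    psa_res.ceac.to_csv(out / "ceac.csv", index=False)

    lines = base.summary_lines()
    lines.append(f"CEAC at ${spec.model.wtp_per_qaly:,.0f}/QALY: "
                 f"{psa_res.ceac_at(spec.model.wtp_per_qaly):.3f} "
                 f"({n_iter} draws, {psa_res.n_failed} failed)")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    manifest = RunManifest(
        config_digest=spec.digest(),
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        accrual_flags={
            "ll_convention": spec.curves["combo"]["pfs"].ll_convention,
            "vial_rounding": spec.model.vial_rounding,
            "subsequent_therapy_mode": spec.model.subsequent_therapy_mode,
            "terminal_cost_mode": spec.model.terminal_cost_mode,
            "half_cycle_correction": spec.model.half_cycle_correction,
            "ct_every_n_cycles": spec.model.ct_every_n_cycles,
        },
        outputs=[str(out / f) for f in
                 ("basecase.csv", "tornado.csv", "psa_draws.csv",
                  "ceac.csv", "summary.txt")],
    )
    manifest.write(out / "manifest.json")
    return manifest
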