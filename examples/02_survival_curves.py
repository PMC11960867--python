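"""Survival machinery: curve summaries and AIC-based family selection.

Prints the model-implied median survival of the four shipped loglogistic
curves, then simulates a censored cohort from one of them and lets the
fitter rank all five parametric families by AIC.
"""

from tnbc_cea import SimSpec, compare_families, median_survival, simulate_ipd
from tnbc_cea.config import default_curves
from tnbc_cea.io import fit_results_frame

curves = default_curves()
print("model-implied median survival (months):")
for arm, eps in curves.items():
    for ep, params in eps.items():
        print(f"  {arm:8s} {ep.upper():3s}: {median_survival(params):6.2f}"
              f"   (lambda={params.lambda_}, gamma={params.gamma_})")
print("  -> OS medians 31.0 (combination) and 23.0 (control) sit within 10%"
      " of the trial's reported 33.10 and 23.50 months.")

print("\nfitting all five families to a simulated control-arm OS cohort:")
ipd = simulate_ipd(SimSpec("loglogistic", 0.04349, 0.53309, n=400,
                           admin_censor_months=40.0, dropout_rate=0.004,
                           seed=1))
comp = compare_families(ipd)
print(fit_results_frame(comp.results).to_string(index=False,
                                                float_format=lambda x: f"{x:.4f}"))
print("  -> lower AIC = better fit; the generating family should rank"
      " at or near the top.")
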