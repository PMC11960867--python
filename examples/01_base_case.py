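"""Deterministic base case: per-arm discounted totals and the ICER.

Runs the three-state cohort model for both treatment strategies with the
shipped inputs and prints the results table.  The final line answers the
policy question: does the combination buy its extra QALYs for less than
$100,000 each?
"""

from tnbc_cea import load_config

spec = load_config(None)          # shipped base case
result = spec.base_case()
print("\n".join(result.summary_lines()))
print()
print("Reading: each arm's lifetime discounted cost, life-years and "
      "quality-adjusted life-years over 5 years; the ICER is the extra "
      "cost per extra QALY of adding toripalimab.")
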