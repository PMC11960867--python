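# Methods

## Model structure

A three-state cohort model (progression-free, progressed, dead) on 21-day
cycles over a 5-year horizon; `n_cycles = ceil(5 × 365.25 / 21) = 87`, with
the 87th cycle truncated so accrual ends exactly at 60 months.  State
occupancy is evaluated by partitioned survival directly from the two fitted
curves of each arm: PFS occupancy is S_PFS at the cycle boundary, the dead
fraction is 1 − S_OS, and PD is the difference.  This is the only occupancy
rule uniquely determined by published curve parameters (no progression-to-
death hazard is published), and it coincides exactly with a Markov chain in
which everyone alive faces the OS hazard and PFS exits are residual.
Per-cycle transition probabilities 1 − S((t+1)u)/S(tu) are exposed for
inspection.  Deaths in a cycle are apportioned between PFS and PD
proportionally to previous-boundary occupancy when computing incident
progressions — the neutral choice, used only for the progression-flow and
tunnel bookkeeping, not for occupancy itself.  A tunnel tracks PD occupancy
by whole cycles since progression so post-progression costs can be capped.

State membership is counted at cycle start; a half-cycle correction
(boundary averaging) is available as `half_cycle_correction` but off by
default, matching the common default of cycle-tree modelling tools.

## Survival curves

All five AFT families (exponential, Weibull, Gompertz, lognormal,
loglogistic) share a (λ per month, γ dimensionless) parameterization.  The
base-case curves are loglogistic.  Published loglogistic "λ, γ" pairs are
ambiguous; three readings exist:

1. S(t) = [1 + (λt)^(1/γ)]⁻¹ — γ is the AFT **scale** σ, the convention of
   Stata's `streg`, median 1/λ (**default**, `ll_convention="aft_scale"`);
2. S(t) = [1 + (λt)^γ]⁻¹ — γ as the shape exponent, median also 1/λ
   (`ll_convention="exponent"`);
3. S(t) = [1 + λ·t^γ]⁻¹ — median (1/λ)^(1/γ), hundreds of months for these
   parameter values; rejected outright.

Readings 1 and 2 both reproduce the trial's reported OS medians (31.0 and
23.0 months vs 33.10 and 23.50), so the median is not diagnostic between
them.  They differ in the tail: under the scale convention the shape
exponent is 1/γ ≈ 1.6–1.9 > 1 (light tail, ~5–25% alive at 5 years), under
the exponent convention it is ≈ 0.53–0.64 < 1 (very heavy tail, ~23–40%).
Only the scale convention yields arm totals and an incremental QALY
difference consistent with the reference results this model is built to
reproduce (ΔQALY ≈ 0.293 vs ≈ 0.11 under the exponent reading), and it is
what a Stata AFT fit actually reports — hence the default.  The switch is a
config field, and the engine accepts any family so that, e.g., a lognormal
scenario can be run (on AIC grounds the lognormal is competitive for these
data; the loglogistic base case follows the published parameter set).

Fitting maximizes the right-censored log-likelihood Σ_events log f +
Σ_censored log S with Nelder-Mead restarted from a fixed 3×3 grid of (λ, γ)
multipliers {0.5, 1, 2}² around the exponential events/exposure rate —
deterministic by construction.  The exponential MLE is closed-form.
Gompertz shapes are restricted to γ > 0 (proper distributions only).  AIC =
2k − 2·loglik with k = 1 (exponential) or 2 ranks families; ties break by
family declaration order.

## Kaplan-Meier reconstruction

`reconstruct_ipd` implements the Guyot algorithm: within each risk-table
interval it guesses a censoring count, spreads those censorings uniformly,
assigns events at the digitized drop times to match each survival step
given the running at-risk count, and iterates the guess until the computed
number at risk matches the next table entry (raising an infeasibility error
if that requires negative censoring).  When a total event count is
supplied, censoring in the final interval is calibrated to match it;
otherwise no post-table censoring is assumed beyond administrative
censoring of survivors at end of follow-up.  Because the source figures'
digitized coordinates are not published, validation is by round trip on
synthetic cohorts: simulate → digitize (KM + 6-monthly risk table) →
reconstruct → refit, requiring sup-distance ≤ 0.02 between the two KM
curves and parameter recovery within 10% at n = 300.

## Economic inputs and accrual

All prices in US dollars; utilities 0.76 (PFS) and 0.55 (PD); grade ≥3
leukopenia and neutropenia enter once, in cycle 0, as incidence-weighted
costs and utility decrements (one cycle's duration — the published inputs
give no episode length).  Accrual per cycle, discounted at
(1.05)^(−t years) from the cycle-start time:

* **Drug acquisition** on PFS occupancy while the cycle starts before the
  2-year cap: toripalimab 240 mg per cycle (combination only) plus
  nab-paclitaxel 125 mg/m² on days 1 and 8.  With the default
  `vial_rounding=True`, each administration is priced in whole 100 mg vials
  (1.84 m² → 230 mg → 3 vials); a fractional-pricing flag exists because
  wastage policy is a genuine unknown that shifts costs by ~6%.
* **Monitoring** on alive occupancy: laboratory work every cycle, CT plus
  tumor imaging every third cycle (~9-week restaging; cadence configurable).
* **Subsequent therapy** at the published $6,533.66 per cycle.  The default
  accrues it on *all* PD occupancy, which is what the reference per-arm
  totals imply; the alternative `subsequent_therapy_mode="capped_35w"`
  honours the stated 35-week limit via the tunnel (10–11 full cycles plus a
  ⅔-prorated one) and lowers both arms' costs by ~$85k.  The per-cycle
  price is decomposed as a carboplatin + gemcitabine doublet (AUC 2 and
  1000 mg/m², days 1 and 8) plus a fixed non-drug remainder, so the unit
  prices and body-surface area act as genuine sensitivity inputs while the
  base value reproduces the printed total exactly.
* **Terminal care** $85,904 per death, attached to incident deaths in their
  cycle (discounted); a per-cohort undiscounted variant exists as a flag.

Life-years are discounted alive-occupancy time; QALYs weight occupancy by
state utility.  Every flag combination used for a report is written to its
manifest.

## Sensitivity analysis

Survival parameters are never varied (no published ranges).  One-way
analysis reruns the full base case at each parameter's published bounds
(mostly ±25%, a few asymmetric).  PSA treats each range as a 95% interval,
sd = (high − low)/3.92, and builds method-of-moments gamma (costs), beta
(probabilities/utilities) and normal (BSA) distributions with mean at the
base value; draws are joint and independent across parameters, one
substream per parameter in sorted name order for seed-stable output.  The
CEAC reports P(w·ΔQ − ΔC ≥ 0) on a $0–1.2M grid in $10k steps.  The default
2,000 iterations keep the full test suite under a minute; production runs
at 10⁵ are a CLI flag away (`cea psa --n-iter 100000`) and change the CEAC
by less than Monte-Carlo noise at 2,000 (binomial SE ≤ 0.011).

## Synthetic data

`simulate_ipd` draws event times by inverse-CDF from any family, censors by
the minimum of an administrative cutoff and exponential dropout, and
`km_from_ipd` (product-limit via lifelines) produces the digitized-figure
inputs for reconstruction tests.  Default cohort sizes (300/150) are
synthetic, trial-like magnitudes — the source trial's exact arm sizes are
not part of the inputs.  The generator samples marginal PFS and OS curves
independently, as the cohort model itself uses them; it does not emulate
patient-level PFS/OS correlation, informative censoring, or digitization
noise, so passing round-trip tests demonstrate algorithmic correctness, not
robustness to sloppy digitization.

## Numerical choices and known limitations

* Parameter-recovery checks compare the mean estimate over five fixed
  replicate seeds with the truth at 5%: the single-draw sampling error of
  λ̂ is ≈3% at n = 5,000 for the heavy-tailed families, so a one-seed check
  would test luck rather than the estimator.
* Curve crossings (S_PFS > S_OS) are tolerated to 0.02 and clipped;
  anything larger raises an error naming the cycle.
* Occupancy conservation and tunnel-sum identities hold to 1e−9 per cycle.
* The reference per-arm life-year totals cannot all be matched
  simultaneously under any single occupancy convention; the combination
  arm's published LY total is internally inconsistent with its own
  published increment (2.20 + 0.41 ≈ 2.61, which this model reproduces,
  vs a printed 2.68).  Costs, QALYs, the incremental cost and the ICER are
  reproduced within the documented tolerances.
* No PD-L1 subgroup modelling (no subgroup parameters are published), no
  efficiency frontier beyond the two strategies, no half-cycle-corrected
  tunnel costs, and no indirect/societal costs or inflation adjustment.
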