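# Methods

## Disease course and cycle mechanics

The model is a discrete-time individual-level (microsimulation) state
transition model with a one-year cycle, 70 cycles, cohort entry at age 40,
and certain death at age 110. Within each cycle events happen in a fixed
order: (1) accrual of the cycle's cost and utility at the cycle start, at
full-cycle weight, discounted by `(1+r)^(−k)`; (2) a death draw from the
age-indexed life table; (3) for survivors in active-disease states without
a prior complication, sequential complication draws; (4) the state
transition. There is **no half-cycle correction**; a patient dying in cycle
k keeps that cycle's accrual and accrues nothing afterwards. This ordering
is shared bit-for-bit by the scalar patient stepper, the vectorised cohort
simulator and the expectation oracle.

Structural wiring (all config-exposed in `StructuralRules`):

* **Entry.** Everyone starts the initial ATD course; the first year carries
  the acute-care cost ($1,125.15), the second the annual ATD cost, both at
  the on-treatment utility (0.86).
* **ATD failure** (5% over 1.5 y, annualised 0.0336/y) models escalation to
  definitive therapy (radioactive iodine / surgery) and routes to lifelong
  hypothyroidism (annual cost $250.37, utility 0.9479). By default it also
  applies while on long-term ATD after relapse (`atd_failure_in_relapse`).
* **ATD-induced hypothyroidism** (2.9% over 10.2 y, annualised 0.00288/y)
  applies in every ATD-taking state and routes the same way.
* **Remission** follows 2 failure-free course years. Relapse risk (52.8%
  over 3.73 y, annualised 0.1823/y) applies for a 5-year window; surviving
  it relapse-free confers long-term remission, absorbing apart from death.
* **Relapse** moves to long-term ATD (annual cost $48.87, utility 0.86)
  with an annual `subsequent_remission_prob` chance of regaining remission
  (clock reset). This probability is the single calibratable control-arm
  structural parameter.
* **Complications** are sampled only in active-disease states (initial
  course, retreatment course, long-term ATD after relapse).
  Thyroid-associated orbitopathy is a one-time 25% risk spread over the
  first two active years as a per-year hazard `1 − (1−0.25)^(1/2)`; the
  other five are annual incidences at their stated values. At most one
  complication is tagged per patient — draws are sequential in the listed
  order, first hit wins — and from onset it adds its annual cost and caps
  utility at `min(state utility, complication utility)` for life.
* **Monitoring.** The control arm accrues one full thyroid-function-test
  (TFT) fee ($92.44) every alive cycle.

## The digital arm

The monitoring solution enters the model through four channels:

1. **Early relapse detection.** A relapse is caught within the cycle with
   probability equal to the device sensitivity (0.8713). Detected relapses
   restart a 2-year ATD retreatment course — same failure, hypothyroidism
   and (non-orbitopathy) complication hazards as the initial course, but no
   repeat acute-care cost — and then re-enter remission with a fresh
   relapse-free clock. Undetected relapses proceed to long-term ATD as in
   the control arm. The alternative reading, "detected relapse stays in
   remission with a reset clock", was rejected: it converts ~80% of
   remitters into long-term remitters, an implausibly strong effect for a
   monitoring device.
2. **Effect multipliers.** `effect_relapse_multiplier` (θp ∈ (0, 1])
   scales the annual relapse probability and `effect_remission_uplift`
   (θr ∈ [1, 5]) scales the subsequent-remission probability. They encode
   the hypothesised behavioural benefit (adherence, earlier titration) and
   are resolved by calibration, never assumed.
3. **Monitoring economics.** Twelve monthly subscription fees ($30/month
   base) accrue every alive cycle for life, plus one scheduled confirmatory
   TFT visit per year at `fee × (1 − visit_cost_reduction)` (the
   visit-cost-reduction scenarios use 0/10/20/30%).
4. **False positives.** In non-hyperthyroid states (remission, long-term
   remission, hypothyroid) an extra full-fee TFT visit occurs with annual
   probability `1 − specificity` (specificity 0.8378).

With sensitivity 0, specificity 1, zero fee and neutral multipliers the two
arms are identical, and under common random numbers (both arms share one
seed and a fixed 11-draw-per-cycle layout) they produce bit-identical
trajectories — the null-intervention equivalence test.

## Expectation oracle

`cohort_expectation` computes the exact expectation of the same process by
expanding every clock into tunnel states: course year × retreatment flag ×
relapse-free year × ever-relapsed flag × complication tag (147 alive states
at default settings, plus classification-resolved death buckets). The
occupancy vector is propagated cycle by cycle with the identical event
ordering; expected discounted cost/QALYs are inner products with accrual
vectors. Microsimulation means must lie within 3 Monte-Carlo SE of the
oracle (a standing acceptance property), and the oracle must match the
closed-form geometric-series results of the toy configurations to 1e−10.
Deterministic analyses (tornado, fee threshold, calibration) run on the
oracle so parameter rankings and roots carry no simulation noise.

## Background mortality

The package ships a synthetic parametric stand-in for national all-cause
mortality: a Gompertz–Makeham hazard `μ(x) = a + b·e^(ηx)` with defaults
a = 5×10⁻⁴, b = 3×10⁻⁵, η = 0.095, giving q₄₀ ≈ 0.00184 and residual life
expectancy at 40 of ≈ 39 years — calibrated qualitatively to modern
East-Asian longevity. A real life table can be supplied as an (age, qx)
CSV via the config (`mortality.kind: file`); missing old ages are carried
forward to closure at 110. Disease states carry **no excess mortality** by
default, since no disease-specific values are published for this model;
this is the main feature of real data the generator does not emulate, and
passing tests therefore validate the engine and the economics machinery,
not the absolute survival of a real hyperthyroid cohort (see Limitations).

## Parameter uncertainty

Ranges are interpreted as central 95% intervals, sd = range/3.92. PSA
distributions are moment-matched: beta (α, β solved from mean and sd) for
probabilities, utilities and test characteristics; gamma (shape = (mean/sd)²,
scale = sd²/mean) for costs. Fitted means reproduce the base values
exactly; sampled moments are verified against 3 Monte-Carlo SE. Degenerate
rows (a perfect reference test at 100%) are treated as fixed. One-way DSA
varies each parameter with a genuine range to its bounds on the oracle;
parameters without a range are skipped and logged. The PSA samples every
non-fixed parameter per draw and re-runs both arms with common random
numbers; the default scale is 10,000 × 10,000 with a fast 1,000 × 1,000
mode used by the acceptance script.

## Calibration

`subsequent_remission_prob` is fitted first by bounded golden-section
search on [0, 0.5] against the control arm's long-term-remission
classification share; then (θr, θp) are fitted on a 9×9 grid over
[1, 5] × [0.2, 1] with Nelder–Mead refinement against the digital arm's
long-term-remission and relapse shares. The loss is squared share error on
the oracle only — economics never enter, so ΔC, ΔE and the ICER remain
genuine predictions. Classification assigns each patient the first
ever-experienced category in the priority order complication →
hypothyroid → long-term remission → relapse-on-long-term-ATD, else
"other".

Under this wiring the default targets sit partly outside the attainable
range: the control long-term-remission share has a floor of ≈ 19.6% at
`subsequent_remission_prob = 0` (the published target is 17.48%), and the
complication incidences concentrate 55–66% of patients in the
complication class, which caps the relapse class near 1% in both arms, far
below the published shares used as digital-arm targets. Calibration then
returns the best boundary values with `converged = False` and full
residuals — by design, rather than silently absorbing the discrepancy into
other parameters.

## Numerical choices

* Discounting: `(1+r)^(−k)` from cycle 0; rate 0.045 base, 0.03–0.05 in DSA.
* Fee threshold: bisection on [0, 200] $/month to $0.01 absolute; ΔC is
  exactly affine in the fee under the oracle because survival is
  arm-independent, which yields the affine-shift consistency check.
* ICERs are suppressed (flagged) when |ΔE| < 10⁻⁹ or under dominance;
  tornado rows keep signed ΔC/ΔE so spans stay defined.
* Complication tie-breaks: sequential draws in the declared order.
* Random numbers: one `numpy` PCG64 stream per cohort, 11 uniforms per
  patient-cycle in a fixed layout regardless of arm or state.

## Limitations

* The structural wiring between the published inputs (state list, hazards,
  costs) is not itself published; the rules above are the simplest
  consistent wiring, all config-exposed, but other wirings reproduce the
  published headline economics more closely than this one. In particular
  the absence of disease-specific excess mortality lengthens discounted
  lifetimes (≈ 18.5 discounted alive-years), which raises the lifetime
  subscription cost and with it the incremental cost and ICER relative to
  the published values; the calibration targets are partly unattainable as
  described above. These gaps are reported (unconverged calibration flags,
  failing tolerance-band checks), not patched.
* No treatment attrition or adherence decay; no monthly-cycle or
  continuous-time variant; no currency conversion or inflation adjustment
  (inputs are taken as 2022 USD); no EVPI/EVSI and no correlated PSA
  sampling.
* The prevalence input is housed for completeness but unused: the cohort
  is all-incident by construction.
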