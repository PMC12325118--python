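# thyrocea

A decision-analytic Markov **microsimulation** model of hyperthyroidism
management, comparing usual care against care supported by a wearable /
mobile thyroid-function digital monitoring solution, from a health-care
system perspective (2022 USD, South Korean inputs).

The package is aimed at health-economics researchers who want a tested,
config-driven reimplementation of this class of model: every input is a
declared parameter with a base value, range and PSA distribution; the
disease course is simulated patient-by-patient *and* solved exactly by a
deterministic expectation oracle; and all standard cost-effectiveness
outputs (QALYs, ICER, NMB, tornado, CEAC, threshold analysis) are produced
by library functions or a thin CLI.

## Model

A hypothetical cohort of 10,000 patients, aged 40 at diagnosis, moves
through annual cycles (70 cycles, death certain at age 110) across the
states: initial antithyroid-drug (ATD) course → remission →
long-term remission, with relapse → long-term ATD, ATD failure or
ATD-induced hypothyroidism → lifelong hypothyroidism, major complications
(thyroid-associated orbitopathy, atrial fibrillation, heart failure,
osteoporosis, fracture, thyroid cancer) tagged during active disease, and
death from an age-indexed life table. Multi-year probabilities (e.g. ATD
failure 5% over 1.5 y, relapse 52.8% over 3.73 y) are cycle-aligned under a
constant-hazard assumption, `p_annual = 1 − (1 − p)^(1/t)`. Costs and
utilities accrue per cycle and are discounted at 4.5%/year:

    E = Σ_k u(s_k) · (1+r)^(−k),   C = Σ_k c(s_k) · (1+r)^(−k)

The digital arm pays a monthly subscription for life, detects relapses
early with the device's sensitivity (routing them into a short ATD
re-treatment course instead of long-term ATD), triggers false-positive
confirmatory visits at 1 − specificity, and acts on the disease course
through two calibratable multipliers (relapse probability; subsequent
remission). Strategies are compared by ICER = ΔC/ΔE and net monetary
benefit `NMB = E·WTP − C` at a willingness-to-pay of US $32,255/QALY.

Deterministic one-way sensitivity analysis, the subscription-fee threshold
search and calibration all run on the exact oracle (no Monte-Carlo noise);
the probabilistic sensitivity analysis re-samples every non-fixed parameter
(beta for probabilities/utilities, gamma for costs, ranges read as 95%
intervals) and re-runs both arms under common random numbers.

See `docs/methods.md` for the full structural rules, calibration procedure,
synthetic mortality model and known limitations.

## Worked example

```sh
$ thyrocea run --seed 42 --out out/
control: C=$7,095.14 E=16.38 QALY | digital: C=$13,222.61 E=16.65 QALY | dC=$6,127.47 dE=0.27 ICER=22,835.09 $/QALY
```

Per person and discounted, usual care costs ≈ $7,095 and yields 16.38
QALYs; the digitally supported strategy costs ≈ $13,223 (the lifetime
subscription dominates the difference) and yields 0.27 extra QALYs, i.e.
≈ $22,835 per QALY gained — cost-effective at the $32,255/QALY threshold.
`out/summary.json` holds the same numbers at full precision with
Monte-Carlo standard errors, `out/cohort.csv` the per-patient outcomes, and
`out/manifest.json` the config digest and seed that reproduce the run
byte-for-byte.

```sh
$ thyrocea threshold
dominant below $2.53/month
```

Below a subscription of $2.53/month the digital arm is cheaper *and* more
effective (dominant). Other subcommands: `calibrate`, `dsa` (tornado CSV +
plot), `psa [--fast]` (draws, CEAC, ICE scatter), `scenario
--visit-reduction 0/10/20/30`, `export-config`.

As a library:

```python
from thyrocea import simulate_cohort, compare_arms
from thyrocea.calibration import calibrated_config

cfg, _ = calibrated_config()
ce = compare_arms(simulate_cohort(cfg, "control", seed=1),
                  simulate_cohort(cfg, "digital", seed=1), cfg.economics)
print(ce.icer)
```

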