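# bflact

An agent-based simulation of breastfeeding intent, initiation and
maintenance among low-income primiparous women enrolled in WIC (the US
Special Supplemental Nutrition Program for Women, Infants, and
Children), built for public-health modelers who want to estimate the
population impact of breastfeeding-promotion interventions before
fielding them.

Each simulated woman carries sociodemographics, a Beta-distributed
breastfeeding-knowledge score `K`, four binary intervention exposures,
and scheduled barrier events. She forms prenatal intent with
`P(intent) = expit(a + 1.17 K)`, initiates breastfeeding at childbirth
with `P(init) = expit(b + 2.0 · intent + 0.155 · BFHI)`, and then moves
daily through the path-dependent feeding states
`EXCLUSIVE > PARTIAL > FORMULA` (formula is absorbing) under three
residual monthly transition rates (0.016, 0.059, 0.139) plus two
barriers — lactation problems (87.4% of women, early-clustered onset)
and return to work — resolved by support-dependent decision trees:
support from both a lactation consultant and a partner means she
continues as before; less support means a step down. Intervention
scenarios raise the coverage of five levers (knowledge education, BFHI,
postpartum counseling, partner support, workplace support) and are
scored by eight outcome rates: intent, initiation, and any/exclusive
breastfeeding at 1, 3 and 6 months, averaged over 100 Monte-Carlo
replicates of a fresh n = 3,845 synthetic cohort.

The survey data behind the original cohort are not public, so
`bflact.population` synthesizes cohorts from the published marginal
distributions; `bflact.calibration` fits the unpublished parameters
(two intercepts, the exclusive share at initiation, the
lactation-problem onset timescale) to the published baseline rates, and
also provides the full RMSE grid search over the three transition
rates. See `docs/methods.md` for the model, assumptions and design
choices.

## Worked example

```python
from bflact import Scenario, calibrate_baseline, run_scenario, synergy

# Calibrate the unpublished parameters against the published baseline.
baseline = calibrate_baseline(seed=1, reps_per_point=10)
print(f"exclusive share at initiation: {baseline.exclusive_share:.3f}")
print(f"onset timescale (months):      {baseline.calibration.onset_scale:g}")

base = run_scenario(Scenario(), baseline, replicates=100, seed=1)
ptr = run_scenario(Scenario(name="PTR@0.95", cov_partner=0.95),
                   baseline, replicates=100, seed=1)
print(f"any BF at 6 months, baseline:     {base.mean('any_bf_6m'):.2f}%")
print(f"any BF at 6 months, partner@95%:  {ptr.mean('any_bf_6m'):.2f}%")
```

prints

```
exclusive share at initiation: 0.729
onset timescale (months):      0.3
any BF at 6 months, baseline:     54.72%
any BF at 6 months, partner@95%:  60.11%
```

Calibration finds that 72.9% of initiators start exclusively and that
lactation problems cluster within the first few weeks (mean onset
0.3 months past discharge). Raising partner-support coverage from its
67.7% baseline to 95% lifts 6-month any-breastfeeding point prevalence
by about 5.4 percentage points — partner support keeps women from
stepping down when lactation problems strike, and most of them strike
early, so the protection compounds over the whole horizon.

A command-line interface wraps the same library:

```bash
bflact simulate --seed 1 --replicates 100 --out results/
bflact calibrate --seed 1 --out results/          # grid table + best fit
bflact sensitivity --parameter beta_bfhi --seed 1 --out results/
bflact published-grid --seed 1 --out results/         # full scenario grid
```

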