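# Model and methods

`bflact` is an agent-based model of infant-feeding decisions among
low-income primiparous women enrolled in WIC, covering the window from
late pregnancy to six months postpartum. It exists to reproduce, from
published marginal distributions and parameter values alone, a baseline
breastfeeding trajectory and a set of intervention-coverage experiments,
and to let users run their own coverage scenarios.

## The behavioral model

Each woman passes through three stages.

**Intent (pregnancy).** A Bernoulli draw with
`P(intent) = expit(a + beta_k * K + peer_weight * f)`, where `K` is her
breastfeeding-knowledge score (Beta-distributed on [0, 1], baseline mean
0.67, SD 0.10), `beta_k = 1.17` is the published coefficient for the
effect of breastfeeding education on intention, and `f` is the fraction
of her network peers who intend to breastfeed. Hooks for
sociodemographic coefficients exist but default to zero: no coefficients
are published, so heterogeneity enters through knowledge (and optionally
the network). `peer_weight` defaults to 0, which makes the homophilous
peer network inert unless a user opts in; no network statistics are
published, so reproduction of the outcome tables must not depend on
invented network parameters.

**Initiation (childbirth).** A Bernoulli draw with
`P(initiate) = expit(b + 2.0 * intent + 0.155 * bfhi)`, where 0.155 is
the published coefficient for Baby-Friendly Hospital Initiative
practices. The intent coefficient is not identifiable from published
marginals; 2.0 is a configurable convention, and the intercept `b` is
calibrated. Initiation is logistic rather than intent-gated because the
published initiation rate (92.96%) exceeds the intent prevalence
(88.50%): some women initiate without prenatal intent. Initiators start
either exclusively or partially breastfeeding; the split is a single
calibrated proportion.

**Maintenance (postpartum, day 3 to month 6).** Feeding status follows
the strict step-down order exclusive > partial > formula; no transition
ever raises the level, and formula feeding is absorbing (breastfeeding
interrupted for more than a few days does not resume). Each day a woman
faces:

- *Residual hazards*: the three monthly transition proportions
  (exclusive→formula 0.016, partial→formula 0.059, exclusive→partial
  0.139) converted to daily probabilities by compounding,
  `q = 1 - (1 - p_month)^(1/30.4375)`. Competing exclusive-state risks
  are resolved by one uniform draw against cumulative per-day
  probabilities, which keeps each monthly marginal correct to first
  order.
- *A lactation problem* (87.4% of women, at most one event): with
  support from both a lactation consultant and a partner she continues
  unchanged; with exactly one source of support she steps down one
  level; the unspecified no-support branch defaults to the same single
  step (configurable to two). A single event therefore never moves an
  exclusive breastfeeder to formula outright — consistent with the
  published exclusive trajectory, whose decline after month 1 is almost
  exactly the residual-rate compound survival, and with the size of the
  published counseling/partner lever effects (a two-step branch roughly
  triples them).
- *Return to work* (category probabilities 9.1% at 0–2 months, 14.4% at
  3–5, 13.0% at ≥6, 63.5% not employed; times uniform within category):
  a supportive workplace leaves the status unchanged, otherwise one step
  down (configurable).

Barriers scheduled on the same day as a residual transition are resolved
first (lactation problem, then return to work, then the residual draw);
the ordering is fixed for reproducibility and immaterial at daily
resolution.

### Lactation-problem onset timing

Only the 0–6-month cumulative incidence of lactation problems is
published, not their timing. Timing matters: the published baseline
trajectory drops steeply in month 1 (initiation 92.96% → any-BF 77.41%)
and then declines gently, which is unreachable when the barrier hazard
is flat in time (a uniform-onset variant bottoms out around RMSE 4pp
with any-BF at 1 month ~8pp too high). Clinically, lactation problems —
latch pain, nipple trauma, perceived insufficient supply — cluster in
the first weeks postpartum. The default onset distribution is therefore
an exponential decay from hospital discharge (day 3), truncated at 6
months, whose timescale (in months) is identifiable from the trajectory
shape and is fitted during calibration (about 0.3 months at the default
settings). A uniform-onset option remains available
(`lactation_onset_dist="uniform"`).

## Synthetic cohorts

The survey records behind the original cohort are not deposited, so
cohorts are synthesized from published marginals: age ~ Normal(28.1,
6.4) truncated to [15, 50]; high-school-or-above 63.5% (the published
education marginals sum to 101%; the complement of the
less-than-high-school figure is used); Hispanic 85.0%; income ≤100% FPL
48.4%; exposure coverages BFHI 11.4%, counseling 78.12%, partner
support 67.74%, workplace support 52.05% (where the outcome tables print
more decimal places than the parameter table, the former are used).
Fields are independent by default — the original model used joint
records, but no joint distribution is published — with an optional
Gaussian-copula rank-correlation layer over the nine sampled fields for
users who have association estimates. Knowledge-score Beta shapes come
from the method of moments, which requires `sd^2 < mean*(1-mean)`.

What the generator deliberately does not emulate: sociodemographic
correlations (off by default), any dependence of barrier occurrence or
exposure on sociodemographics (not published), multiparous women, and
household structure beyond the partner flag. Passing tests therefore
show that the *model logic* reproduces published aggregate rates under
independent marginals, not that it captures joint-distribution effects
in real WIC data.

## Calibration

Three published targets are matched exactly by construction: the intent
and initiation intercepts are root-found (Brent) so the *expected*
population rates over a 50,000-woman reference cohort equal 88.50% and
92.96%.

The six postpartum rates (any and exclusive breastfeeding at 1, 3, 6
months) identify the exclusive share at initiation and the onset
timescale. For any fixed parameter set, every population rate is linear
in the exclusive share — each woman's trajectory depends only on her own
starting state and random stream — so each candidate simulates only the
two extreme starting states under common random numbers and the
best-fitting share has a closed least-squares form. If a calibration
target specifies the share explicitly, it is held fixed instead.

The three residual transition rates are *not* re-estimated by default:
the published values are adopted directly. The attribution of the
postpartum decline between barriers and residual rates is weakly
identified from six aggregate rates (an almost flat RMSE valley trades
the exclusive→formula rate against the partial→formula rate), yet that
attribution controls how much leverage the coverage levers have, so
re-estimating it can silently change every intervention effect while
fitting the baseline equally well. Keeping the published rates pins the
attribution to the published model.

The from-scratch procedure is nevertheless fully implemented
(`calibrate`, or `calibrate_baseline(search_rates=True)`): an RMSE grid
search over the published tested ranges (exclusive→formula 0.004–0.08,
partial→formula 0.02–0.5, exclusive→partial 0.015–0.3), 10 points per
axis, jointly with the onset-timescale axis, followed by one 9-point
refinement pass spanning ±1 coarse step around the incumbent; ties
break toward the smallest rates, and a boundary optimum logs a warning.
Each grid point reuses per-replicate cohorts, prenatal draws and barrier
schedules (common random numbers), so the search costs two postpartum
passes per point per replicate. Parameter-recovery tests confirm the
search finds a true on-grid triple from simulated targets; recovery of
off-grid truths is limited by the flat valley above, which is a property
of the model family, not of the search.

## Experiments

Five levers: knowledge (KNWL — shifts the Beta mean of the knowledge
score, SD kept at 0.10 clipped to feasibility), BFHI, counseling (COUL),
partner support (PTR) and workplace support (WP). Coverage levers are
raised by "top-ups": each unexposed woman flips with probability
`(target - base) / (1 - base)`, so existing exposures are preserved and
interventions only add coverage. The published grid
(`scenario_grid_published`) is one baseline, 15 single-lever scenarios
(5 levers × levels 80/90/95%) and 15 nested packages (KNWL ⊂ KNWL+BFHI ⊂
… ⊂ all five).

A scenario run draws a fresh cohort per replicate (default 100
replicates of n = 3,845, the original training-sample size) and reports
replicate means with Monte-Carlo standard errors for the eight outcomes:
intent, initiation, and any/exclusive breastfeeding point prevalence at
1, 3 and 6 months. "Any breastfeeding at month t" is point prevalence of
exclusive-or-partial status at t — the reading consistent with the
published declining trajectories, though the original outcome section
defines "any" as ever-fed. Replicate random streams are shared across
scenarios by default (common random numbers), which leaves means
unbiased and sharpens contrasts; a per-scenario independent-stream mode
is available. Synergy of a package is
`(package - baseline) - sum(singles - baseline)` for a chosen outcome.

Sensitivity sweeps vary one effect coefficient (`beta_knowledge` over
1.0–1.5 or `beta_bfhi` over 0.1–0.5) with all levers at 95% coverage
under shared streams. One known limit: with the intent intercept
calibrated at `beta_knowledge = 1.17`, raising the coefficient to 1.5
adds 0.33 × 0.95 to the linear predictor and moves intent by about
+2pp — more than the ~0.8pp spread the original sensitivity table
reports (a table whose default-value row, inconsistently, reprints the
baseline-coverage outcomes). No logistic intent model of this form can
reproduce that flatness; the corresponding flatness test is expected to
fail on that single cell and the package does not hide it.

## Numerical and design choices

- Daily time steps (month = 30.4375 days; horizon day 183; evaluation at
  days 30, 91, 183); the ≤2-day hospital stay and month-1 evaluation are
  representable with negligible discretization error.
- All randomness flows from integer seeds through named
  `numpy.random.SeedSequence` streams (cohort, scenario application,
  network, trajectories; one spawn per replicate). Within a run, each
  woman's draws come from a uniform matrix row assigned by agent-id
  rank, so results are bitwise reproducible and invariant to cohort row
  order.
- The postpartum day loop is a numba kernel (early exit at the absorbing
  state) with an identical pure-Python fallback.
- Degenerate inputs are rejected with messages naming the bound
  (infeasible Beta moments, non-normalized category probabilities,
  coverage below baseline, missing sociodemographic fields).
- Problem sizes in the test suite and acceptance script (100 replicates
  of n = 3,845; 50,000-woman reference cohorts; 150,000-woman
  micro-simulations for analytic cross-checks) were chosen to keep
  Monte-Carlo error well under the comparison tolerances.

## Known limitations

- Decision-tree branches beyond the published one-support rule, the
  lactation-onset timing, the intent→initiation coefficient and the
  exclusive share at initiation are reconstructions constrained by
  published outputs, not observed inputs; alternative settings are
  exposed as configuration.
- Workplace-lever effects run ~2–3pp stronger than the published level-3
  row, and the five-lever package inherits that excess; the return-to-
  work tree details that would close the gap are not published.
- Peer influence is implemented (homophilous random graph, intent-stage
  influence with a provisional-pass scheme) but quantitatively
  uncalibrated, and off by default.
- No cost-effectiveness, subgroup targeting, calendar-time rollout, or
  significance testing between scenarios.
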