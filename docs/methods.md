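# Methods

## The decision problem

Endovascular coiling of unruptured intracranial aneurysms (UIA) carries a
substantial risk of aneurysm *recanalization* — coil compaction that
re-exposes the aneurysm to rupture — of roughly 24.4% over six years.  A
health technology innovation (HTI, e.g. a mesenchymal-stem-cell coating)
administered during the index procedure that reduces the recanalization
rate by a relative risk reduction (RRR) `x` at a price `y` may or may not
be worth paying for.  `coilcea` implements a two-arm probabilistic Markov
cohort model, from the healthcare-payer perspective in 2018 USD, that
quantifies this trade-off: standard coiling versus standard coiling plus
the adjunct.

## Model structure

Patients enter at age 45 immediately after an index coiling procedure and
are followed for 60 six-month cycles (30 years).  A state is
`(kind, i, mRS)` where `kind` is coiled (secured), unsecured (a
recanalized or de novo aneurysm present and untreated), or a one-cycle
aSAH (rupture) tunnel; `i` = 1..4 counts coiling procedures; functional
status is mRS 0, mRS 1–2 or mRS 3–5 and can only worsen (ratchet).  Death
is absorbing.  There are 4·3·2 + 12 + 1 = 37 states.

Per cycle, from a coiled state: recanalization (multiplied by `1 − RRR` in
the adjunct arm while the index coil, i = 1, is the most recent) and de
novo aneurysm formation pool into the unsecured state; background
mortality competes.  From unsecured: rupture (1.4%/year) or retreatment;
after the fourth procedure no further retreatment is offered.  A rupture
kills 12.4% before hospital; admissions spend one cycle in the tunnel
(utility 0.41, hospital cost $93,440) and then die (26.5%) or return to a
coiled state with status ratcheted by the aSAH outcome, with the
procedure count capped at 4.  Competing events are resolved by
proportional-hazards allocation (convert each probability to a hazard,
share the combined event probability proportionally, keep the exact
survivor mass), which guarantees non-negative residuals.

Three structural conventions matter and are exposed as configuration
rather than hard-coded, because the published description leaves them
open; the defaults were selected so the model reproduces the full pattern
of published results (base-case Table, discount-rate reruns, the
price-elasticity line and the efficacy scenarios) simultaneously:

- **Cycle rescaling** (`ModelConfig.prob_conversion`, default `"linear"`):
  probabilities quoted per 1 or 6 years are rescaled to the half-year
  cycle proportionally (`p · cycle/period`), the common spreadsheet
  convention.  Constant-hazard conversion (`"hazard"`,
  `1 − (1−p)^(cycle/period)`) is available and is the default of the
  standalone `per_cycle_probability` utility.
- **Recanalization window** (`recan_window_years`, default 5.5):
  recanalization risk applies while model time is inside the surveillance
  window over which the cumulative 24.4% was counted, i.e. recanalization
  is an early-years phenomenon of the coiled aneurysm, not a lifelong
  constant hazard.  Without a window the unsecured state becomes
  near-absorbing (≈40% occupancy by year 15) and both the incremental
  QALY and the discount-rate profile of the ICER depart from the
  published results by factors of 2–3.  De novo aneurysm risk (0.6%/year)
  runs over the whole horizon.
- **Retreatment** (`retreat_conditional`, default True): the published
  6-year retreatment probability (9.1%) is interpreted as marginal over
  all coiled patients, so the rate applied to unsecured occupants is the
  conditional probability 9.1/24.4 ≈ 37% per 6 years.  Applying 9.1%
  directly to unsecured occupants (`False`) leaves recanalized aneurysms
  untreated for decades.

Background (all-cause) mortality uses a bundled abridged life table —
approximate US 2018 rates blended ≈70/30 female/male, since UIA cohorts
are predominantly female — and competes in every alive non-tunnel state.
It can be disabled.

## Accrual conventions

No half-cycle correction: QALYs and state costs accrue on start-of-cycle
occupancy at that cycle's discount factor `(1+r)^(−t)`, `r` = 1.5%/year
for both costs and QALYs.  Utilities: mRS-specific values (the mRS 0
utility is age-banded, 0.87/0.85/0.86/0.84, all four bands moving with one
shared draw offset); unsecured patients additionally carry the untreated-
aneurysm disutility (−0.07); the tunnel cycle accrues the aSAH utility.
Transition-attached costs (retreatment procedures by complication
outcome, aSAH admissions) are charged in the cycle the transition occurs,
computed from source-state flows.  The index procedure is applied at
cycle 0 as a complication mixture (mild 4.8%, moderate-severe 2.2%, death
2.0%) with matching procedure costs, plus the undiscounted adjunct price
($10,000 base case) in the adjunct arm only.  aSAH survivors' retreatment
is covered by the admission cost (no second procedure cost, avoiding
double counting).

## Parameter uncertainty

Each of the 25 parameters carries a published mean, SE and family.
Probabilities are Beta, moment-matched from (mean, SE) — the printed
moments, not the raw event counts, are authoritative, since several rows
pool multiple sources.  The aSAH hospital cost is Gamma.  The untreated-
aneurysm disutility is a Beta-distributed magnitude returned negative.
Costs and utilities marked as ordered truncated normals are sampled as
normal(mean, SE) truncated to natural bounds (costs ≥ 0, utilities in
[0, 1]); members of an order group share one quantile per joint draw
(comonotone severity), which preserves the care-cost and utility marginal
means to <0.2% while making ordering violations rare; the rare crossing
draws are redrawn.  Two caveats are inherent rather than bugs: (i) the
procedure-cost SEs are 0.5–0.9× their means, so 0-truncation plus
ordering shifts their realised means upward (≈34.1k/52.6k/88.0k against
printed 30.0k/47.2k/65.3k); a moment-corrected parent (see
`truncated_normal_from_moments`) is provided as a diagnostic but is not
used for sampling, because the uncorrected convention reproduces the
published results and the corrected one does not; (ii) exact moment
matching and 100% ordering cannot hold together for these parameters
under any copula.

The adjunct efficacy follows a configurable distribution: uniform on
[0, 1] in the base case (expected RRR 50%, halving the 6-year
recanalization rate from 24.4% to 12.2%), normals truncated to [0, 1]
(means 10/30/50%, SDs 2/5/15%) in scenarios, or a fixed value for the
price sweeps.

A draw whose categorical splits (procedural complications, aSAH outcomes)
sum above 1 is rejected and redrawn, preserving marginals; with the
published table this essentially never happens.

## Monte Carlo design

One PSA iteration draws a joint parameter realization and propagates it
through both arms (common random numbers; the engine is vectorized over
draws, so 7,000 iterations of both arms take about a second).  The
headline run uses 7,000 iterations — a convergence profile flags
stability once the running ICER changes <1% between 500-iteration
checkpoints, which occurs well before 7,000 — replicated on independent
substreams (`numpy` `SeedSequence.spawn`) to attach 95% credible
intervals (2.5th/97.5th replicate percentiles) to every statistic.  All
randomness flows from a single seed.

Decision analytics: ICER = mean ΔC / mean ΔE; CEAC(λ) = fraction of
iterations with λ·ΔE − ΔC > 0 (ties count as not cost-effective); EVPI =
E[max(0, INB)] − max(0, E INB), scaled to the treated population by
15,925 procedures/year × 10 years, undiscounted.  EVPPI uses brute-force
two-level nesting (outer draws of the focal parameter, inner expectation
over the rest; defaults 500–1,000 per level); nested estimators are
biased upward when the inner loop is small, which should be kept in mind
when comparing against estimates of unknown inner size.  The maximum
cost-effective price at fixed RRR is the upper median of λ·ΔE − ΔC
(price excluded), floored at 0 — exact because the price enters the
incremental cost once, additively, undiscounted; a price-bisection oracle
cross-checks it in the tests.  The tornado analysis pins one variable at
its published sensitivity bounds (±2 SE unless overridden) while all
others stay stochastic.

## Verification

An independent patient-level microsimulation implements the same
state dynamics with its own event-sampling loop and its own competing-
risk arithmetic (no shared propagation code).  Cohort and microsimulation
means must agree within 3 Monte Carlo SEs on both arms, at the published
table and on randomly generated valid parameter tables
(`random_parameter_table`, which jitters means/SEs within family-feasible
ranges while preserving orderings and split-validity).  A mutation test
confirms the comparison has teeth (disabling discounting in one engine is
detected at >3 SE).

## What the synthetic machinery does and does not show

Random tables exercise schema validation, sampling feasibility, engine
conservation laws and cohort–microsim agreement across a broad parameter
region; they do not calibrate to any real registry, so passing tests
demonstrates internal consistency and faithful implementation of the
stated model, not clinical validity of the inputs.  Reproduced study
values depend on the three structural conventions above; sensitivity to
them is exactly one configuration flag away.

## Problem sizes used in the checks

The bundled end-to-end checks run at desk scale: 8–10 replicates of 7,000
iterations for the base case, 2,000 iterations per point for the
101-point price sweep, 20,000–60,000 iterations for single-scenario
ICERs, 500×500 for EVPPI, and 6,000-patient microsimulations per draw for
the 20-draw agreement check.  These sizes put the Monte Carlo error of
each statistic well inside the tolerance it is compared at.

## Known limitations

- The exact published model structure (detailed state diagram, cycle
  conversion, truncation rules, EVPPI loop sizes) is not public; the
  conventions here are a reconstruction validated against the published
  results jointly, and the nested-MC EVPPI reproduces the published
  qualitative ordering (large at $50k, ≈0 at $150k) but not the printed
  $50k magnitude, which is consistent with inner-loop bias in the original
  estimate (see the EVPPI note above).
- Single starting age, no aneurysm-morphology risk stratification, no
  societal-perspective costs, no repeat adjunct administration at
  retreatment — all outside the model's scope.
- The life table is an approximate blend; any abridged table can be
  substituted via configuration.
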