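# coilcea

Cost-effectiveness modelling of recanalization-reducing adjuncts to
endovascular coiling of unruptured intracranial aneurysms (UIA).

Coiled aneurysms recanalize — the coil mass compacts and blood re-enters —
in roughly 24.4% of patients over six years, restoring rupture risk and
driving retreatments.  A health technology innovation (HTI) given during
the index procedure (e.g. a mesenchymal-stem-cell coil adjunct) that
reduces recanalization by a relative risk reduction *x* at price *y* poses
a concrete adoption question for payers and a pricing question for
developers.  `coilcea` answers both with a probabilistic Markov cohort
model (healthcare-payer perspective, 2018 USD): 37 health states over
`(treatment status, number of coilings 1–4, mRS functional status)`, 60
six-month cycles from age 45, costs and QALYs discounted at 1.5%/year.

For strategies *s* ∈ {standard, standard + HTI} sharing each parameter
draw θ, the package computes

- **ICER** = E[ΔC]/E[ΔE], the incremental cost per QALY gained;
- **CEAC(λ)** = P(λ·ΔE − ΔC > 0), the probability the adjunct is
  cost-effective at willingness-to-pay λ;
- **EVPI / EVPPI**, the (partial) expected value of perfect information,
  E[max(0, INB)] − max(0, E INB), population-scaled by 15,925
  procedures/year × 10 years;
- the **maximum cost-effective price** at efficacy *x*: the upper median
  of λ·ΔE − ΔC₀ (price excluded), giving the value-based pricing line
  *y* ≤ slope · *x* via a through-origin fit over the 0–100% efficacy
  sweep;
- probabilistic one-way (tornado), discount-rate and efficacy-scenario
  analyses.

A vectorized cohort engine propagates thousands of parameter draws at
once (a 7,000-iteration two-arm PSA takes ~1 s), and an independent
patient-level microsimulation with no shared propagation code
cross-validates every accrual rule.

## Worked example

```bash
python examples/base_case.py
```

```
Discounted 30-year means per patient (2018 USD):
  standard coiling : cost   308,351  QALYs 18.053
  coiling + adjunct: cost   315,247  QALYs 18.202
ICER: 46,431 $/QALY [45,848, 47,397]
  (incremental cost per quality-adjusted life-year gained; the
   adjunct is good value at thresholds above this number)
P(cost-effective at $50,000/QALY): 0.493   10-year US population EVPI: $408,757,815
P(cost-effective at $100,000/QALY): 0.693   10-year US population EVPI: $244,096,597
P(cost-effective at $150,000/QALY): 0.782   10-year US population EVPI: $173,567,265
```

At its default $10,000 price and uniformly uncertain efficacy, the
adjunct costs ~$6,900 more per patient and returns ~0.15 QALYs, an ICER
just under $50,000/QALY — a genuine coin-flip at that threshold (CEAC
0.49), which is why the information value is large.  The other examples
(`price_elasticity.py`, `scenarios_and_discounting.py`,
`value_of_information.py`, `validate_engine.py`) cover the pricing line
(max price ≈ 20,500·RRR at $50k/QALY), the bounded-normal efficacy and
discount-rate scenarios, EVPPI for the baseline recanalization risk, and
the cohort-versus-microsimulation check.

A thin CLI wraps the same library surface:

```bash
coilcea base-case --out runs/base --seed 1
coilcea elasticity --out runs/price --seed 1 --iterations 2000
coilcea tornado --out runs/tornado --seed 1 --iterations 2000
coilcea scenarios --out runs/scen --seed 1
coilcea evppi --out runs/evppi --seed 1
coilcea validate --out runs/check --seed 1
```

Each command writes CSV/JSON outputs plus a `manifest.json`; a YAML
config (`--config`) can override any model setting (cycle length,
horizon, discounting, adjunct price and efficacy distribution,
thresholds, background mortality, structural conventions).  An empty
config reproduces the base case.

Model structure, accrual conventions, distribution handling and known
limitations are documented in [docs/methods.md](docs/methods.md).

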