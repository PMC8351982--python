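"""How much is a recanalization-reducing adjunct worth, per unit of efficacy?

Sweeps the relative risk reduction (RRR) from 0 to 100% and computes, at
each value, the highest price that keeps the probability of
cost-effectiveness at or above one half; a through-origin line summarises
the sweep as `max price = slope x RRR`.
"""

from coilcea import ModelConfig, default_parameter_table, elasticity_curve

specs = default_parameter_table()
config = ModelConfig()

for threshold in (50_000.0, 100_000.0, 150_000.0):
    curve = elasticity_curve(specs, config, threshold,
                             n_iterations=1_000, seed=2)
    p30 = curve.max_price[30]
    print(f"threshold ${threshold:>9,.0f}/QALY: "
          f"max price = {curve.fitted_slope:,.0f} x RRR; "
          f"at RRR 30% a payer should pay at most ${p30:,.0f}")

print()
print("Example reading: a developer expecting a 30% relative reduction in")
print("recanalization can price the adjunct up to the value above and still")
print("be adopted by a payer using the corresponding willingness-to-pay.")
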