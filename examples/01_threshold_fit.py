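"""Estimate the relative size at onset of flowering for one species.

Simulates 500 individuals of a species whose true threshold is S_0.5 = 0.216
(the published worked example: logistic intercept 7.378, slope 4.812), then
re-estimates the threshold from the raw (diameter, flowered) records.
"""

from precocity import s50, simulate_species_observations, species_maturity

# the closed-form transformation of the published example fit
print(f"s50 from the worked-example coefficients: {s50(7.378, 4.812):.3f}")

obs = simulate_species_observations(
    s50_true=0.216, b=4.812, dbh95=30.3, per_species_n=500, seed=7,
    species_id="demo",
)
est = species_maturity(obs, "demo")
print(f"simulated individuals: {est.n}")
print(f"95th-percentile diameter: {est.dbh95_cm:.1f} cm")
print(f"fitted logistic: a = {est.fit.a:.3f}, b = {est.fit.b:.3f}")
print(f"estimated s50: {est.s50:.3f}  (truth 0.216)")
# s50 is the relative size (diameter / 95th-percentile diameter) at which
# half the individuals are expected to bear flowers.
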