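"""Power by simulation for the carrier-frequency design threshold.

For a cohort of 387 with AUD prevalence 0.60, how detectable is a large
carrier effect (OR = 10) as a function of carrier frequency? This is the
design computation behind restricting individual-rCNV tests to variants
above ~2% carrier frequency.
"""

from foundercnv.stats import power_by_simulation

n, prevalence, odds_ratio = 387, 0.60, 10.0
print(f"n = {n}, prevalence = {prevalence}, carrier OR = {odds_ratio}, "
      f"alpha = 0.05 (two-sided), 10,000 replicates per point")
for freq in (0.005, 0.01, 0.022, 0.03, 0.05):
    est = power_by_simulation(n, prevalence, freq, odds_ratio,
                              alpha=0.05, reps=10_000, seed=41)
    print(f"  carrier frequency {freq:5.3f}: power {est.power:.2f} "
          f"(+/- {est.se:.3f})")

null = power_by_simulation(n, prevalence, 0.022, 1.0, reps=10_000, seed=42)
print(f"null check (OR = 1): rejection rate {null.power:.3f} ~ alpha")
# Power rises steeply with carrier frequency; at OR = 1 the rejection rate
# sits at the nominal alpha, confirming the test is calibrated.
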