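"""Power and sample size for a validation cohort via Fisher's exact test.

Exact unconditional power: enumerate binomial(n1, p1) x binomial(n2, p2)
outcomes and sum the probability of tables whose two-sided Fisher p-value
is at most alpha. The sample-size search inverts this at a fixed 0.4:0.6
group allocation (the observed active:remission ratio).
"""

from ftirchem import fisher_power, required_sample_size

p1, p2, alpha = 0.4, 0.6, 0.05

pw = fisher_power(79, 120, p1, p2, alpha)
print(f"power at n1=79, n2=120 (0.4 vs 0.6, two-sided alpha {alpha}): {pw:.4f}")

spec = required_sample_size(p1, p2, alpha, power=0.8, allocation=(0.4, 0.6))
print(f"smallest total for 80% power (exact): {spec.total} "
      f"({spec.n1} + {spec.n2}), achieved power {spec.achieved_power:.4f}")

approx = required_sample_size(p1, p2, alpha, power=0.8, allocation=(0.4, 0.6),
                              method="normal")
print(f"uncorrected normal approximation:     {approx.total} "
      f"({approx.n1} + {approx.n2})")
print("\nThe exact Fisher test is conservative, so it needs more samples "
      "than the normal approximation for the same nominal power.")
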