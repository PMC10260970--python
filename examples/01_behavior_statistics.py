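"""Behavioral test statistics: binomial z tests and effect sizes.

Reproduces the style of analysis used for four-arm conditioning data:
did a fish's success rate beat chance, and do two groups differ?
"""

from fosnet import (
    benjamini_hochberg,
    binom_one_sample_z,
    binom_two_sample_z,
    partial_eta_squared,
)

# A fish chose the rewarded arm 5 times in 8 trials; chance among three
# scoreable options is 1/3.  Z > 1.64 means better than chance at p < .05.
res = binom_one_sample_z(5, 8, 1 / 3)
print(f"learning criterion: Z = {res.statistic:.2f}, p = {res.p_value:.3f}")

# Probe test with the trained (congruent) cue: 8 correct of 9 vs 50% chance.
res = binom_one_sample_z(8, 9, 0.5)
print(f"congruent probe:    Z = {res.statistic:.2f}, p = {res.p_value:.3f}, "
      f"OR = {res.effect_size['OR']:.2f}")

# Congruent vs incongruent groups (unpooled-SE two-sample z): the success
# difference of 0.514 is what the test calls delta p-hat.
res = binom_two_sample_z(8, 9, 3, 8)
print(f"congruent vs incongruent: Z = {res.statistic:.2f}, p = {res.p_value:.3f}, "
      f"delta p-hat = {res.effect_size['delta_p_hat']:.3f}")

# Effect size of a t test (t(15) = 2.55) as partial eta-squared: the share
# of residual variance the effect explains.
print(f"partial eta squared for t(15) = 2.55: "
      f"{partial_eta_squared(2.55**2, 1, 15):.3f}")

# Benjamini-Hochberg adjustment of three planned comparisons.
print("BH-adjusted [0.01, 0.02, 0.03] ->",
      [round(float(p), 3) for p in benjamini_hochberg([0.01, 0.02, 0.03])])
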