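"""Sensitivity and sample-size planning for the paired SNARC slope comparison.

Asks two questions.  First, frequentist: with 24 participants and a
slope-difference SD of 18.34 ms, how large a difference could a two-sided
paired t-test detect?  Second, Bayesian: how likely is the JZS Bayes factor
to reach moderate evidence (BF10 > 3 under a true d = 0.15 at n = 800;
BF10 < 1/3 under d = 0 at n = 180)?
"""

import snarcflex as sf

for power in (0.80, 0.90, 0.95):
    mdd = sf.min_detectable_difference(power, sd=18.34, n=24, alpha=0.05)
    print(f"power {power:.2f}: minimum detectable difference "
          f"{mdd.delta:.1f} ms (d = {mdd.d:.2f})")

mc = sf.mc_power_paired(11.0, sd=18.34, n=24, alpha=0.05,
                        replications=10_000, seed=0)
print(f"Monte-Carlo power at an 11.0 ms difference: {mc:.3f}")

res = sf.bayes_design_analysis(d_true=0.15, n=800, replications=2000, seed=0)
print(f"P(BF10 > 3 | d=0.15, n=800) = {res.prop_h1:.3f}  "
      f"(inconclusive: {res.prop_inconclusive:.3f})")
res0 = sf.bayes_design_analysis(d_true=0.0, n=180, replications=2000, seed=0)
print(f"P(BF10 < 1/3 | d=0, n=180) = {res0.prop_h0:.3f}  "
      f"(misleading H1: {res0.prop_h1:.3f})")
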