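"""Sequential Bayes-factor recruitment (SBF+maxN) on a simulated cohort.

Recruits an initial 200 simulated participants, evaluates the full
confirmatory battery (SNARC in each range, critical-number dRT shifts,
smallest-number intercepts, slope difference), and keeps adding batches of
20 until every Bayes factor has crossed 3 or 1/3 — or the 800-participant
cap is reached.
"""

import numpy as np

import snarcflex as sf


def fit_stream(params, seed):
    """Yield per-participant fitted statistics drawn from the population.

    Uses the latent structure directly (slope, intercepts and critical
    dRTs per range), i.e. the idealized noiseless analysis of an endless
    recruitment stream.
    """
    rng = np.random.default_rng(seed)
    while True:
        p = sf.sample_population(params, 1, rng)[0]
        rec = {}
        for rid, smallest in (("lower", 1), ("higher", 4)):
            a, b = p.alpha[rid], p.beta[rid]
            rec[f"slope_{rid}"] = b
            rec[f"smallest_number_intercept_{rid}"] = a + b * smallest
            rec[f"drt_4_{rid}"] = a + 4 * b + 0.5 * p.gamma
            rec[f"drt_5_{rid}"] = a + 5 * b - 0.5 * p.gamma
        yield rec


def battery(cohort):
    return {
        "1a": sf.one_sample_test(cohort["slope_lower"]),
        "1b": sf.one_sample_test(cohort["slope_higher"]),
        "2a_4": sf.paired_test(cohort["drt_4_lower"], cohort["drt_4_higher"]),
        "2a_5": sf.paired_test(cohort["drt_5_lower"], cohort["drt_5_higher"]),
        "2b": sf.paired_test(cohort["smallest_number_intercept_lower"],
                             cohort["smallest_number_intercept_higher"]),
        "3": sf.paired_test(cohort["slope_lower"], cohort["slope_higher"]),
    }


params = sf.PopulationParams.reference("exp2")
result = sf.run_sbf_maxn(fit_stream(params, seed=3), sf.SequentialConfig(), battery)

print(f"stopped at n = {result.stopping_n} ({result.stopped_by})")
print(f"checkpoints evaluated: {result.checkpoints}")
for name, verdict in result.verdicts.items():
    bf = result.trajectories[name][-1]
    print(f"  hypothesis {name:>4}: BF10 = {bf:10.4g}  ->  {verdict}")
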