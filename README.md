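# snarcflex

Analysis toolkit for parity-judgement SNARC experiments that present the
same numbers in different ranges.

The SNARC effect (Spatial–Numerical Association of Response Codes) is the
finding that people answer small numbers faster with the left hand and
large numbers faster with the right.  Per participant it is quantified by
regressing dRT — the mean right-hand minus left-hand RT per number — on
number magnitude: the more negative the slope β in

    dRT(m) = α + β·m (+ γ·parity(m)),

the stronger the effect.  When the critical numbers 4 and 5 appear both in
a lower range (0–5, or 1–5 without 3) and a higher range (4–9, or 4–8
without 6), comparing slopes, critical-number dRTs and predicted dRTs at
each range's smallest magnitude separates *relative*-magnitude dependency
(the mapping follows a number's position within the range) from
*absolute*-magnitude dependency.  The optional γ term on a ±0.5 parity
contrast is the MARC effect (odd–left/even–right association).

The package provides, as a plain Python library:

* **Synthetic cohorts** — the full counterbalanced block design and an
  ex-Gaussian trial-level RT generator whose expected dRT structure is
  exactly the regression model above, with realistic errors,
  anticipations and lapses (`simulate_cohort`).
* **The preregistered exclusion pipeline** — participant screening,
  trial filters (practice/missing/incorrect/<200 ms/>1500 ms), iterative
  per-participant ±3 SD trimming, 75%-valid and empty-cell criteria, with
  a full audit report (`preprocess`).
* **SNARC estimation** — dRT tables, per-participant OLS fits, group
  summaries, refits excluding selected numbers (`compute_drt`, `fit_all`).
* **Default Bayes factors, implemented from scratch** — JZS one-sample /
  paired t-test BF with Cauchy prior scale 0.707, the default Pearson
  correlation BF, effect-size helpers and evidence categories
  (`one_sample_test`, `paired_test`, `correlation_bf`).
* **Design analysis** — noncentral-t and Monte-Carlo power, minimum
  detectable differences, Bayes-factor design analysis, and SBF+maxN
  sequential recruitment with optional stopping
  (`min_detectable_difference`, `bayes_design_analysis`, `run_sbf_maxn`).

## Worked example

`examples/` contains one short script per capability.  For instance,
`python examples/design_analysis.py` prints:

```
power 0.80: minimum detectable difference 11.0 ms (d = 0.60)
power 0.90: minimum detectable difference 12.7 ms (d = 0.69)
power 0.95: minimum detectable difference 14.1 ms (d = 0.77)
Monte-Carlo power at an 11.0 ms difference: 0.801
P(BF10 > 3 | d=0.15, n=800) = 0.905  (inconclusive: 0.075)
P(BF10 < 1/3 | d=0, n=180) = 0.907  (misleading H1: 0.006)
```

The first block answers the frequentist sensitivity question: with 24
participants and a slope-difference SD of 18.34 ms, only between-range
slope differences of at least 11 ms could be detected at 80% power — far
larger than typical SNARC slopes themselves.  The second block is the
Bayesian sampling plan: 800 participants give a 0.90 probability of
moderate evidence (BF10 > 3) for a true effect of d = 0.15, while 180
suffice for a 0.90 probability of moderate evidence for a true null.

End-to-end, `python examples/simulate_and_fit.py` simulates 60
participants of the orthogonal-stimulus experiment, runs the exclusion
pipeline (printing the per-stage tallies, ≈5.6% errors, ≈2% lapses,
≈2% trimmed) and recovers group slopes near the generating −10.17 /
−5.92 ms.  `python examples/sequential_recruitment.py` runs the six-test
confirmatory battery under SBF+maxN and stops, for its example seed, at
n = 220 with five hypotheses at "strong H1" and the smallest-number
intercept test at "moderate H0".

A thin CLI mirrors the library (`snarcflex simulate|preprocess|fit|test|
design|run`), e.g.:

```bash
snarcflex run --experiment exp2 --n 200 --seed 1 --out results/ --plots
```

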