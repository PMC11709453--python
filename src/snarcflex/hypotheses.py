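"""The preregistered hypothesis battery over fitted SNARC statistics.

Confirmatory tests (all two-sided, JZS prior scale 0.707):

* 1a / 1b — one-sample test of SNARC slopes against zero in the lower /
  higher range (a SNARC effect exists in each range).
* 2a_4 / 2a_5 — paired test of the dRT of critical number 4 / 5 between
  ranges (relative-magnitude dependency of the number-line mapping).
* 2b — paired test of smallest-number intercepts between ranges
  (absolute-magnitude dependency of the mapping).
* 3 — paired test of SNARC slopes between ranges (absolute-magnitude
  dependency of the strength of the SNARC effect).

Exploratory: paired test of mean-number intercepts; default correlation
Bayes factor between the two ranges' slopes; one-sample test of the MARC
coefficient (orthogonal-stimulus experiment only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import (DEFAULT_RSCALE, BayesResult, correlation_bf,
                    one_sample_test, paired_test)

CONFIRMATORY = ("1a", "1b", "2a_4", "2a_5", "2b", "3")


def pivot_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """One row per participant, columns ``<stat>_<range>``.

    Keeps only participants with fits in both ranges, aligned by id.
    """
    wide = fits.pivot(index="participant_id", columns="range_id")
    wide.columns = [f"{stat}_{rng}" for stat, rng in wide.columns]
    needed = [c for c in wide.columns if c.startswith("slope_")]
    return wide.dropna(subset=needed)


def confirmatory_battery(
    fits: pd.DataFrame, rscale: float = DEFAULT_RSCALE
) -> dict[str, BayesResult]:
    """All six confirmatory Bayesian tests on a fit table."""
    w = pivot_fits(fits)
    return {
        "1a": one_sample_test(w["slope_lower"], rscale),
        "1b": one_sample_test(w["slope_higher"], rscale),
        "2a_4": paired_test(w["drt_4_lower"], w["drt_4_higher"], rscale),
        "2a_5": paired_test(w["drt_5_lower"], w["drt_5_higher"], rscale),
        "2b": paired_test(w["smallest_number_intercept_lower"],
                          w["smallest_number_intercept_higher"], rscale),
        "3": paired_test(w["slope_lower"], w["slope_higher"], rscale),
    }


def exploratory_battery(
    fits: pd.DataFrame,
    rscale: float = DEFAULT_RSCALE,
    include_marc: bool | None = None,
) -> dict[str, BayesResult]:
    """Exploratory tests: mean-number intercepts, slope correlation, MARC."""
    w = pivot_fits(fits)
    out = {
        "mean_number_intercept": paired_test(
            w["mean_number_intercept_lower"],
            w["mean_number_intercept_higher"], rscale,
        ),
        "slope_correlation": correlation_bf(
            float(np.corrcoef(w["slope_lower"], w["slope_higher"])[0, 1]),
            len(w),
        ),
    }
    has_marc = "marc_coefficient_lower" in w.columns and \
        w["marc_coefficient_lower"].notna().any()
    if include_marc is None:
        include_marc = has_marc
    if include_marc:
        # one MARC value per participant: the mean over the ranges in
        # which the joint regression was fitted
        marc = w[["marc_coefficient_lower", "marc_coefficient_higher"]] \
            .astype(float).mean(axis=1).dropna()
        out["marc"] = one_sample_test(marc, rscale)
    return out


def battery_bfs(fits: pd.DataFrame, rscale: float = DEFAULT_RSCALE) -> dict[str, float]:
    """Confirmatory battery as bare BF10 values (for sequential stopping)."""
    return {k: v.bf10 for k, v in confirmatory_battery(fits, rscale).items()}
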