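"""dRT computation and per-participant SNARC regressions.

The SNARC effect is quantified with the repeated-measures regression
approach (Lorch & Myers; applied to SNARC by Fias et al.): for each
participant and each number range, the right-minus-left mean RT difference
(dRT) per number is regressed on number magnitude by ordinary least
squares.  The slope (ms per magnitude unit) measures the SNARC effect —
more negative means stronger.  Optionally a +-0.5 parity contrast enters
as a second regressor, whose coefficient is the MARC effect.

Derived quantities per fit:

* smallest-number intercept: predicted dRT at the range's smallest
  magnitude (where the ranges differ in absolute terms);
* mean-number intercept: predicted dRT at the range's mean magnitude;
* dRT at the critical numbers 4 and 5 (raw cell dRTs, not fitted values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import StimulusSet, parity_code, stimulus_sets

FIT_COLUMNS = [
    "participant_id", "range_id", "slope", "intercept_at_zero",
    "smallest_number_intercept", "mean_number_intercept",
    "drt_4", "drt_5", "marc_coefficient", "numbers_used",
]


@dataclass(frozen=True)
class SNARCFit:
    participant_id: str
    range_id: str
    slope: float
    intercept_at_zero: float
    smallest_number_intercept: float
    mean_number_intercept: float
    drt_4: float | None
    drt_5: float | None
    marc_coefficient: float | None
    numbers_used: tuple[int, ...]


def compute_drt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell dRT table: one row per participant x range x number.

    dRT is the unweighted mean right-hand RT minus mean left-hand RT.
    Raises if any side of any observed cell is empty (the preprocessing
    empty-cell criterion guarantees this cannot happen on its output).
    """
    grouped = trials.groupby(
        ["participant_id", "range_id", "number", "response_side"]
    )["rt_ms"].agg(["mean", "size"]).unstack("response_side")
    means, sizes = grouped["mean"], grouped["size"]
    for side in ("left", "right"):
        if side not in means.columns or means[side].isna().any():
            bad = means.index[means.get(side, pd.Series(np.nan, index=means.index)).isna()]
            raise ValueError(
                f"empty {side}-hand cell(s) encountered: {list(bad[:5])} — "
                "run the preprocessing empty-cell criterion first"
            )
    out = pd.DataFrame({
        "mean_rt_left": means["left"],
        "mean_rt_right": means["right"],
        "n_left": sizes["left"].astype(int),
        "n_right": sizes["right"].astype(int),
    })
    out["drt_ms"] = out["mean_rt_right"] - out["mean_rt_left"]
    return out.reset_index()


def fit_participant_regression(
    drt_rows: pd.DataFrame,
    include_parity: bool = False,
    parity_only: bool = False,
) -> SNARCFit:
    """OLS fit of dRT on magnitude for one participant and one range.

    ``include_parity`` adds the +-0.5 parity contrast as a second regressor
    (the joint fit used for the MARC coefficient); ``parity_only`` fits the
    contrast alone instead of magnitude.  Derived intercepts come from the
    magnitude coefficient and the intercept only.
    """
    rows = drt_rows.sort_values("number")
    numbers = rows["number"].to_numpy(int)
    if len(np.unique(numbers)) < 2:
        raise ValueError("need at least 2 distinct magnitudes to fit a slope")
    y = rows["drt_ms"].to_numpy(float)
    parity = np.array([parity_code(m) for m in numbers])

    if parity_only:
        if np.ptp(parity) == 0:
            raise ValueError("parity contrast is constant; cannot fit parity-only model")
        X = np.column_stack([np.ones_like(parity), parity])
        coef = _ols(X, y)
        slope, intercept, marc = np.nan, np.nan, float(coef[1])
        smallest = mean_int = np.nan
    else:
        cols = [np.ones(len(numbers)), numbers.astype(float)]
        if include_parity:
            if np.ptp(parity) == 0:
                raise ValueError("parity contrast is constant; drop include_parity")
            cols.append(parity)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("perfectly collinear predictors in the dRT regression")
        coef = _ols(X, y)
        intercept, slope = float(coef[0]), float(coef[1])
        marc = float(coef[2]) if include_parity else None
        smallest = intercept + slope * numbers.min()
        mean_int = intercept + slope * numbers.mean()

    cell = dict(zip(numbers, y))
    return SNARCFit(
        participant_id=str(rows["participant_id"].iloc[0]),
        range_id=str(rows["range_id"].iloc[0]),
        slope=slope,
        intercept_at_zero=intercept,
        smallest_number_intercept=float(smallest),
        mean_number_intercept=float(mean_int),
        drt_4=float(cell[4]) if 4 in cell else None,
        drt_5=float(cell[5]) if 5 in cell else None,
        marc_coefficient=marc,
        numbers_used=tuple(int(m) for m in numbers),
    )


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def fit_all(
    drt_table: pd.DataFrame, include_parity: bool = False
) -> pd.DataFrame:
    """Fit every participant x range in a dRT table; tidy fit table out."""
    fits = [
        fit_participant_regression(sub, include_parity=include_parity)
        for _, sub in drt_table.groupby(["participant_id", "range_id"], sort=True)
    ]
    return pd.DataFrame([f.__dict__ for f in fits], columns=FIT_COLUMNS)


def refit_excluding_numbers(
    drt_table: pd.DataFrame,
    excluded_numbers: tuple[int, ...] | list[int],
    include_parity: bool = False,
) -> pd.DataFrame:
    """Re-fit after dropping magnitudes from the analysed set.

    Used e.g. to re-analyse the 0-5 range without the special number 0.
    Smallest- and mean-number intercepts are recomputed on the reduced set.
    """
    reduced = drt_table[~drt_table["number"].isin(list(excluded_numbers))]
    n_left = reduced.groupby("range_id")["number"].nunique()
    if (n_left < 2).any():
        bad = list(n_left.index[n_left < 2])
        raise ValueError(f"fewer than 2 magnitudes remain in range(s) {bad}")
    return fit_all(reduced, include_parity=include_parity)


GROUP_STATS = [
    "slope", "intercept_at_zero", "smallest_number_intercept",
    "mean_number_intercept", "drt_4", "drt_5", "marc_coefficient",
]


def derive_group_estimates(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD across participants of every fitted statistic, per range."""
    for range_id, sub in fits.groupby("range_id"):
        if len(sub) < 2:
            raise ValueError(f"need >= 2 fits per range, got {len(sub)} for {range_id}")
    stats = [c for c in GROUP_STATS if c in fits.columns]
    agg = fits.groupby("range_id")[stats].agg(["mean", "std"])
    agg.columns = [f"{stat}_{fn}" for stat, fn in agg.columns]
    return agg.reset_index()
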