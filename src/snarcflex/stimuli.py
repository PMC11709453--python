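"""Stimulus sets for the parity-judgement task.

Two experiments, each with a lower and a higher single-digit number range:

* ``exp1`` uses 0–5 and 4–9 (the classic ranges; magnitude and parity are
  mildly correlated because 0 is even and the ranges have an odd/even
  imbalance at the contrast-code level).
* ``exp2`` uses 1–5 without 3 and 4–8 without 6; dropping one odd/even
  number per range makes the parity contrast exactly orthogonal to
  magnitude, so SNARC and MARC coefficients can be separated cleanly.

Numbers 4 and 5 appear in both ranges of both experiments; their dRTs are
the basis of the relative- vs absolute-magnitude comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EXPERIMENTS = ("exp1", "exp2")
RANGES = ("lower", "higher")

#: contrast code used for the MARC (parity) regressor
PARITY_ODD = -0.5
PARITY_EVEN = 0.5


def parity_code(number: int) -> float:
    """Contrast code of a number's parity: -0.5 for odd, +0.5 for even."""
    return PARITY_EVEN if number % 2 == 0 else PARITY_ODD


@dataclass(frozen=True)
class StimulusSet:
    """One number range of one experiment."""

    experiment_id: str
    range_id: str
    numbers: tuple[int, ...]
    critical_numbers: tuple[int, ...] = (4, 5)

    @property
    def parity_codes(self) -> tuple[float, ...]:
        return tuple(parity_code(m) for m in self.numbers)

    @property
    def smallest_number(self) -> int:
        return min(self.numbers)

    @property
    def mean_number(self) -> float:
        return float(np.mean(self.numbers))

    @property
    def magnitude_parity_correlation(self) -> float:
        """Pearson correlation between magnitude and the parity contrast."""
        return float(np.corrcoef(self.numbers, self.parity_codes)[0, 1])


_SETS: dict[tuple[str, str], StimulusSet] = {
    ("exp1", "lower"): StimulusSet("exp1", "lower", (0, 1, 2, 3, 4, 5)),
    ("exp1", "higher"): StimulusSet("exp1", "higher", (4, 5, 6, 7, 8, 9)),
    ("exp2", "lower"): StimulusSet("exp2", "lower", (1, 2, 4, 5)),
    ("exp2", "higher"): StimulusSet("exp2", "higher", (4, 5, 7, 8)),
}


def get_stimulus_set(experiment_id: str, range_id: str) -> StimulusSet:
    _check_experiment(experiment_id)
    if range_id not in RANGES:
        raise ValueError(f"unknown range_id {range_id!r}; valid: {RANGES}")
    return _SETS[(experiment_id, range_id)]


def stimulus_sets(experiment_id: str) -> dict[str, StimulusSet]:
    """Both ranges of one experiment, keyed by range id."""
    _check_experiment(experiment_id)
    return {r: _SETS[(experiment_id, r)] for r in RANGES}


def _check_experiment(experiment_id: str) -> None:
    if experiment_id not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment_id {experiment_id!r}; valid: {EXPERIMENTS}"
        )
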