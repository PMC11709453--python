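"""Preregistered exclusion pipeline.

The pipeline runs in a fixed order: participant screening on self-report
metadata, then trial-level filters (practice, missing, incorrect,
anticipations < 200 ms, lapses > 1500 ms, iterative per-participant
+-3 SD trimming), then participant-level criteria (at least 75% valid
experimental trials; no empty number-by-response-side cell in either
range).  Every stage's tally is reported on the number of trials that
entered that stage, i.e. fractions use sequential denominators.

Boundary semantics are inclusive: RTs of exactly 200 ms, exactly 1500 ms,
or exactly at mean +- 3 SD are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import StimulusSet, stimulus_sets

#: screening criteria in the order they are applied; a participant receives
#: the first matching reason code only
SCREEN_ORDER = (
    "incomplete", "non_serious", "age", "environment", "distractions",
    "finger_use", "key_assignment",
)

REQUIRED_META_COLUMNS = (
    "participant_id", "age", "serious", "environment", "distractions",
    "finger_compliance",
)


@dataclass(frozen=True)
class PreprocessConfig:
    min_age: int = 18
    max_age: int = 40
    rt_floor_ms: float = 200.0
    rt_ceiling_ms: float = 1500.0
    sd_multiplier: float = 3.0
    min_valid_fraction: float = 0.75
    environment_exclude: frozenset[str] = frozenset({"very noisy", "extremely noisy"})
    distraction_exclude: frozenset[str] = frozenset({"multiple"})

    def __post_init__(self):
        if not self.rt_floor_ms < self.rt_ceiling_ms:
            raise ValueError("rt_floor_ms must be below rt_ceiling_ms")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must lie in (0, 1]")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")


@dataclass
class PreprocessReport:
    """Audit of every exclusion stage."""

    n_participants_in: int = 0
    participants_screened_out: dict[str, int] = field(default_factory=dict)
    trial_stages: list[dict] = field(default_factory=list)  # name, entered, removed, fraction
    trimming_iterations_max: int = 0
    participants_low_valid: int = 0
    participants_empty_cell: int = 0
    n_analysed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_participants_in": self.n_participants_in,
            "participants_screened_out": dict(self.participants_screened_out),
            "trial_stages": list(self.trial_stages),
            "trimming_iterations_max": self.trimming_iterations_max,
            "participants_low_valid": self.participants_low_valid,
            "participants_empty_cell": self.participants_empty_cell,
            "n_analysed": self.n_analysed,
            "denominators": "sequential (each fraction uses the trials entering its stage)",
        }


def screen_participants(
    meta: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply participant-level self-report screening.

    Returns the included participant ids and a table of exclusions with one
    reason code each (the first matching criterion in the preregistered
    order).  Missing/unknown values never trigger an exclusion.  Optional
    columns ``complete`` and ``key_compliance`` feed the incompleteness and
    key-assignment criteria when present.
    """
    config = config or PreprocessConfig()
    missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"participant metadata misses column(s): {missing_cols}")

    def fails(row, criterion) -> bool:
        if criterion == "incomplete":
            return "complete" in meta.columns and row.get("complete") is False
        if criterion == "non_serious":
            return row["serious"] is False
        if criterion == "age":
            age = row["age"]
            return pd.notna(age) and not config.min_age <= age <= config.max_age
        if criterion == "environment":
            return str(row["environment"]).lower() in config.environment_exclude
        if criterion == "distractions":
            return str(row["distractions"]).lower() in config.distraction_exclude
        if criterion == "finger_use":
            return row["finger_compliance"] is False
        if criterion == "key_assignment":
            return "key_compliance" in meta.columns and row.get("key_compliance") is False
        raise AssertionError(criterion)

    included, exclusions = [], []
    for _, row in meta.iterrows():
        reason = next((c for c in SCREEN_ORDER if fails(row, c)), None)
        if reason is None:
            included.append(row["participant_id"])
        else:
            exclusions.append({"participant_id": row["participant_id"], "reason": reason})
    return included, pd.DataFrame(exclusions, columns=["participant_id", "reason"])


def filter_trials(
    trials: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove practice, missing, incorrect, anticipation and lapse trials.

    Stages run in that order; each tally records how many trials entered
    the stage, how many it removed, and the removed fraction of that
    stage's entry count.
    """
    config = config or PreprocessConfig()
    stages = [
        ("practice", lambda d: d["practice"].astype(bool)),
        ("missing", lambda d: d["missing"].astype(bool) | d["rt_ms"].isna()),
        ("incorrect", lambda d: ~d["correct"].astype(bool)),
        ("too_fast", lambda d: d["rt_ms"] < config.rt_floor_ms),
        ("too_slow", lambda d: d["rt_ms"] > config.rt_ceiling_ms),
    ]
    tallies = []
    out = trials
    for name, mask_fn in stages:
        entered = len(out)
        mask = mask_fn(out)
        removed = int(mask.sum())
        tallies.append({
            "stage": name,
            "entered": entered,
            "removed": removed,
            "fraction": removed / entered if entered else 0.0,
        })
        out = out.loc[~mask]
    return out.reset_index(drop=True), tallies


def trim_outliers(
    trials: pd.DataFrame, sd_multiplier: float = 3.0
) -> tuple[pd.DataFrame, int, int]:
    """Iterative +-k*SD trimming of one participant's RTs.

    Repeatedly removes trials whose RT lies strictly more than
    ``sd_multiplier`` sample SDs from the mean of the remaining trials,
    until a pass removes nothing.  Returns (surviving trials, n removed,
    n passes).  Fewer than two trials are returned unchanged.
    """
    if len(trials) < 2:
        return trials, 0, 0
    rt = trials["rt_ms"].to_numpy(float)
    keep = np.ones(rt.size, dtype=bool)
    iterations = 0
    while True:
        iterations += 1
        vals = rt[keep]
        mean, sd = vals.mean(), vals.std(ddof=1)
        out = keep & (np.abs(rt - mean) > sd_multiplier * sd)
        if not out.any():
            break
        keep &= ~out
        if keep.sum() < 2:
            break
    removed = int((~keep).sum())
    return trials.loc[keep].reset_index(drop=True), removed, iterations


def apply_participant_criteria(
    trials: pd.DataFrame,
    designed_totals: dict[str, int] | int,
    sets: dict[str, StimulusSet],
    config: PreprocessConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Final participant-level criteria after all trial exclusions.

    A participant survives with (a) at least ``min_valid_fraction`` of the
    designed experimental trials remaining and (b) no empty
    (range x number x response side) cell.  ``designed_totals`` is the
    designed experimental trial count per participant (a mapping or one
    shared integer, e.g. 600/400).
    """
    config = config or PreprocessConfig()
    included, exclusions = [], []
    for pid, sub in trials.groupby("participant_id", sort=True):
        total = designed_totals[pid] if isinstance(designed_totals, dict) else designed_totals
        if len(sub) / total < config.min_valid_fraction:
            exclusions.append({"participant_id": pid, "reason": "low_valid_fraction"})
            continue
        if _has_empty_cell(sub, sets):
            exclusions.append({"participant_id": pid, "reason": "empty_cell"})
            continue
        included.append(pid)
    return included, pd.DataFrame(exclusions, columns=["participant_id", "reason"])


def _has_empty_cell(sub: pd.DataFrame, sets: dict[str, StimulusSet]) -> bool:
    counts = sub.groupby(["range_id", "number", "response_side"]).size()
    for range_id, sset in sets.items():
        for number in sset.numbers:
            for side in ("left", "right"):
                if counts.get((range_id, number, side), 0) == 0:
                    return True
    return False


def preprocess(
    trials: pd.DataFrame,
    meta: pd.DataFrame,
    config: PreprocessConfig | None = None,
    experiment_id: str | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full pipeline in its preregistered order."""
    config = config or PreprocessConfig()
    if experiment_id is None:
        experiment_id = str(trials["experiment"].iloc[0])
    sets = stimulus_sets(experiment_id)
    report = PreprocessReport(n_participants_in=meta["participant_id"].nunique())

    included, screened = screen_participants(meta, config)
    report.participants_screened_out = (
        screened["reason"].value_counts().to_dict() if len(screened) else {}
    )
    trials = trials[trials["participant_id"].isin(included)]
    designed_totals = (
        trials[~trials["practice"].astype(bool)]
        .groupby("participant_id").size().to_dict()
    )

    trials, tallies = filter_trials(trials, config)
    report.trial_stages = tallies

    entered_trim = len(trials)
    trimmed_frames, removed_total = [], 0
    for _, sub in trials.groupby("participant_id", sort=True):
        kept, removed, iters = trim_outliers(sub, config.sd_multiplier)
        trimmed_frames.append(kept)
        removed_total += removed
        report.trimming_iterations_max = max(report.trimming_iterations_max, iters)
    trials = pd.concat(trimmed_frames, ignore_index=True) if trimmed_frames \
        else trials.iloc[0:0]
    report.trial_stages.append({
        "stage": "trimming",
        "entered": entered_trim,
        "removed": removed_total,
        "fraction": removed_total / entered_trim if entered_trim else 0.0,
    })

    final_ids, late_exclusions = apply_participant_criteria(
        trials, designed_totals, sets, config
    )
    if len(late_exclusions):
        counts = late_exclusions["reason"].value_counts()
        report.participants_low_valid = int(counts.get("low_valid_fraction", 0))
        report.participants_empty_cell = int(counts.get("empty_cell", 0))
    trials = trials[trials["participant_id"].isin(final_ids)].reset_index(drop=True)
    report.n_analysed = len(final_ids)
    return trials, report
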