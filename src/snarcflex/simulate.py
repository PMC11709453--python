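"""Trial-level simulation of parity-judgement reaction times.

The generative model per trial with number ``m`` in range ``r``:

    RT = exGaussian(mu, sigma, tau) + s/2 * (alpha_r + beta_r*m + gamma*parity(m))

where ``s`` is +1 for a right-side response and -1 for a left-side response,
so the expected right-minus-left difference (dRT) at number ``m`` is exactly
``alpha_r + beta_r*m + gamma*parity(m)`` — the regression structure the
downstream analysis estimates.  The half-effect enters symmetrically so
that side means stay centred on the base RT.

Contaminants: with probability ``error_rate`` the response side is flipped
(an incorrect answer whose RT is still recorded); with probability
``p_fast``/``p_slow`` the RT is replaced by a uniform draw on (50, 200) /
(1500, 5000) ms, emulating anticipations and lapses; with probability
``p_miss`` the response is missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignLayout, build_design, correct_side
from .population import ParticipantParams, PopulationParams, sample_population
from .stimuli import StimulusSet, parity_code, stimulus_sets

TRIAL_COLUMNS = [
    "participant_id", "experiment", "block_index", "block_order", "range_id",
    "key_assignment", "number", "parity", "response_side", "rt_ms",
    "correct", "practice", "missing",
]

META_COLUMNS = [
    "participant_id", "age", "serious", "environment", "distractions",
    "finger_compliance", "block_order",
]


def simulate_trials(
    participant: ParticipantParams,
    design: DesignLayout,
    sets: dict[str, StimulusSet] | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one participant's full session as a tidy trial table."""
    if sets is None:
        sets = stimulus_sets(design.experiment_id)
    for s in sets.values():
        if s.experiment_id != design.experiment_id:
            raise ValueError(
                f"stimulus set {s.range_id} belongs to {s.experiment_id}, "
                f"design to {design.experiment_id}"
            )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    frames = []
    for block in design.blocks:
        for practice, numbers in (
            (True, block.practice_trials),
            (False, block.experimental_trials),
        ):
            if not numbers:
                continue
            frames.append(
                _simulate_block(participant, design, block.index, block.range_id,
                                block.key_assignment, numbers, practice, rng)
            )
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def _simulate_block(p, design, block_index, range_id, key, numbers, practice, rng):
    m = np.asarray(numbers, dtype=int)
    n = m.size
    par = np.where(m % 2 == 0, 0.5, -0.5)
    correct_is_right = np.array(
        [correct_side(x, key) == "right" for x in numbers]
    )
    errors = rng.random(n) < p.error_rate
    is_right = correct_is_right ^ errors
    sign = np.where(is_right, 0.5, -0.5)

    effect = p.alpha[range_id] + p.beta[range_id] * m + p.gamma * par
    base = rng.normal(p.exgauss_mu, p.exgauss_sigma, n) if p.exgauss_sigma > 0 \
        else np.full(n, p.exgauss_mu)
    base = base + (rng.exponential(p.exgauss_tau, n) if p.exgauss_tau > 0 else 0.0)
    rt = np.maximum(base + sign * effect, 1.0)

    # contaminants overwrite the structural RT
    fast = rng.random(n) < p.p_fast
    slow = rng.random(n) < p.p_slow
    rt = np.where(fast, rng.uniform(50.0, 200.0, n), rt)
    rt = np.where(slow & ~fast, rng.uniform(1500.0, 5000.0, n), rt)
    missing = rng.random(n) < p.p_miss
    rt = np.where(missing, np.nan, rt)

    return pd.DataFrame({
        "participant_id": p.participant_id,
        "experiment": design.experiment_id,
        "block_index": block_index,
        "block_order": design.block_order_id,
        "range_id": range_id,
        "key_assignment": key,
        "number": m,
        "parity": par,
        "response_side": np.where(is_right, "right", "left"),
        "rt_ms": rt,
        "correct": ~errors & ~missing,
        "practice": practice,
        "missing": missing,
    })


def simulate_cohort(
    params: PopulationParams,
    experiment_id: str,
    n_participants: int,
    seed: int | None = None,
    repetitions: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns the concatenated trial table and a participant-metadata table.
    Per-participant randomness is split off a single ``SeedSequence``, so
    the output is byte-identical for identical ``(params, seed)``.
    """
    root = np.random.SeedSequence(seed)
    pop_ss, *trial_ss = root.spawn(n_participants + 1)
    cohort = sample_population(params, n_participants, np.random.default_rng(pop_ss))

    trial_frames, meta_rows = [], []
    for participant, ss in zip(cohort, trial_ss):
        rng = np.random.default_rng(ss)
        design = build_design(experiment_id, repetitions,
                              participant.block_order_id, rng)
        trial_frames.append(simulate_trials(participant, design, seed=rng))
        meta_rows.append({
            "participant_id": participant.participant_id,
            "age": participant.age,
            "serious": participant.serious,
            "environment": participant.environment,
            "distractions": participant.distractions,
            "finger_compliance": participant.finger_compliance,
            "block_order": participant.block_order_id,
        })
    trials = pd.concat(trial_frames, ignore_index=True)
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return trials, meta
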