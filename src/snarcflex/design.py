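"""Block design of the parity-judgement experiments.

Each participant completes four blocks, one per combination of number range
(lower/higher) and response-key assignment (MARC-congruent: odd-left,
even-right; MARC-incongruent: the reverse).  Every block starts with two
practice presentations per number and then ``repetitions`` experimental
presentations per number in fully randomized order.  Four counterbalanced
block orders rotate which range/key combination comes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import RANGES, StimulusSet, stimulus_sets

KEY_ASSIGNMENTS = ("congruent", "incongruent")

#: the four counterbalanced block orders: range varies fastest in orders 1-2,
#: key assignment varies fastest in orders 3-4
BLOCK_ORDERS: dict[int, tuple[tuple[str, str], ...]] = {
    1: (("lower", "congruent"), ("higher", "congruent"),
        ("lower", "incongruent"), ("higher", "incongruent")),
    2: (("higher", "congruent"), ("lower", "congruent"),
        ("higher", "incongruent"), ("lower", "incongruent")),
    3: (("lower", "incongruent"), ("higher", "incongruent"),
        ("lower", "congruent"), ("higher", "congruent")),
    4: (("higher", "incongruent"), ("lower", "incongruent"),
        ("higher", "congruent"), ("lower", "congruent")),
}

PRACTICE_REPETITIONS = 2


@dataclass(frozen=True)
class Block:
    index: int
    range_id: str
    key_assignment: str
    practice_trials: tuple[int, ...]
    experimental_trials: tuple[int, ...]


@dataclass(frozen=True)
class DesignLayout:
    experiment_id: str
    block_order_id: int
    repetitions: int
    blocks: tuple[Block, ...]

    @property
    def n_experimental_trials(self) -> int:
        return sum(len(b.experimental_trials) for b in self.blocks)

    @property
    def n_practice_trials(self) -> int:
        return sum(len(b.practice_trials) for b in self.blocks)


def correct_side(number: int, key_assignment: str) -> str:
    """Response side of a correct answer under a key assignment.

    MARC-congruent blocks map odd numbers to the left key and even numbers
    to the right key; incongruent blocks reverse the mapping.
    """
    odd = number % 2 == 1
    if key_assignment == "congruent":
        return "left" if odd else "right"
    if key_assignment == "incongruent":
        return "right" if odd else "left"
    raise ValueError(f"unknown key_assignment {key_assignment!r}")


def build_design(
    experiment_id: str,
    repetitions: int = 25,
    block_order_id: int = 1,
    seed: int | np.random.Generator | None = None,
) -> DesignLayout:
    """Build one participant's full ordered trial list.

    Within-block presentation order is a uniform random permutation drawn
    from ``seed``; practice trials precede the experimental trials of each
    block.  Experimental trials per experiment total
    ``repetitions * n_numbers_per_range * 2`` (600 for exp1 and 400 for
    exp2 at the default 25 repetitions).
    """
    sets = stimulus_sets(experiment_id)  # validates experiment_id
    if repetitions < 0:
        raise ValueError("repetitions must be >= 0")
    if block_order_id not in BLOCK_ORDERS:
        raise ValueError(
            f"block_order_id must be one of {sorted(BLOCK_ORDERS)}, "
            f"got {block_order_id}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    blocks = []
    for idx, (range_id, key) in enumerate(BLOCK_ORDERS[block_order_id]):
        numbers = sets[range_id].numbers
        practice = _randomized_repeats(numbers, PRACTICE_REPETITIONS if repetitions else 0, rng)
        experimental = _randomized_repeats(numbers, repetitions, rng)
        blocks.append(Block(idx, range_id, key, practice, experimental))
    return DesignLayout(experiment_id, block_order_id, repetitions, tuple(blocks))


def _randomized_repeats(
    numbers: tuple[int, ...], repetitions: int, rng: np.random.Generator
) -> tuple[int, ...]:
    trials = np.repeat(numbers, repetitions)
    return tuple(int(x) for x in rng.permutation(trials))
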