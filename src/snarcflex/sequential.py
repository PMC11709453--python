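"""Sampling-plan machinery: sequential Bayes factors and design analysis.

Implements the SBF+maxN recruitment scheme (collect an initial cohort,
re-test a battery of Bayesian hypotheses after every recruitment batch,
stop once every Bayes factor has crossed 3 or 1/3, or at a maximum n),
Monte-Carlo Bayes-factor design analysis (the probability of reaching a
given level of evidence at a given n under a true standardized effect),
and frequentist Monte-Carlo power for paired/one-sample t-tests together
with its noncentral-t closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bayes import DEFAULT_RSCALE, BayesResult, categorize_evidence, jzs_bf10


@dataclass(frozen=True)
class SequentialConfig:
    n_initial: int = 200
    batch_size: int = 20
    n_max: int = 800
    bf_upper: float = 3.0
    bf_lower: float = 1.0 / 3.0

    def __post_init__(self):
        if self.n_initial > self.n_max:
            raise ValueError("n_initial must not exceed n_max")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.bf_lower < 1.0 < self.bf_upper:
            raise ValueError("need bf_lower < 1 < bf_upper")

    def checkpoints(self) -> list[int]:
        pts = list(range(self.n_initial, self.n_max, self.batch_size))
        if not pts or pts[-1] != self.n_max:
            pts.append(self.n_max)
        return pts


@dataclass
class SequentialResult:
    stopping_n: int
    checkpoints: list[int]
    trajectories: dict[str, list[float]]
    verdicts: dict[str, str]
    stopped_by: str  # "all-thresholds" | "max-n"


def _bf_value(result) -> float:
    return result.bf10 if isinstance(result, BayesResult) else float(result)


def run_sbf_maxn(
    data_stream: Iterable,
    config: SequentialConfig,
    analysis_chain: Callable[[pd.DataFrame], dict],
) -> SequentialResult:
    """Sequential recruitment with optional stopping.

    ``data_stream`` yields one analysable participant record (a mapping or
    Series of fitted statistics) at a time; ``analysis_chain`` maps the
    accumulated cohort DataFrame to a dict of hypothesis name -> Bayes
    factor (a float or :class:`BayesResult`).  The battery is evaluated at
    ``n_initial`` and after each batch; recruitment stops once every BF
    lies outside (bf_lower, bf_upper), or at ``n_max``.
    """
    stream = iter(data_stream)
    cohort: list = []

    def take(n_target: int) -> None:
        while len(cohort) < n_target:
            try:
                cohort.append(next(stream))
            except StopIteration:
                raise RuntimeError(
                    f"data stream exhausted at n={len(cohort)} "
                    f"before reaching n={n_target}"
                ) from None

    trajectories: dict[str, list[float]] = {}
    checkpoints_seen: list[int] = []
    stopping_n, stopped_by = config.n_max, "max-n"
    last_bfs: dict[str, float] = {}
    for n in config.checkpoints():
        take(n)
        bfs = {k: _bf_value(v) for k, v in analysis_chain(pd.DataFrame(cohort[:n])).items()}
        if not bfs:
            raise ValueError("analysis_chain returned an empty hypothesis battery")
        checkpoints_seen.append(n)
        for k, v in bfs.items():
            trajectories.setdefault(k, []).append(v)
        last_bfs = bfs
        if all(v >= config.bf_upper or v <= config.bf_lower for v in bfs.values()):
            stopping_n, stopped_by = n, "all-thresholds"
            break
    else:
        stopping_n = checkpoints_seen[-1]
    return SequentialResult(
        stopping_n=stopping_n,
        checkpoints=checkpoints_seen,
        trajectories=trajectories,
        verdicts={k: categorize_evidence(v) for k, v in last_bfs.items()},
        stopped_by=stopped_by,
    )


@dataclass(frozen=True)
class DesignAnalysisResult:
    n: int
    d_true: float
    replications: int
    prop_h1: float        # fraction of replications with BF10 > bf_upper
    prop_h0: float        # fraction with BF10 < bf_lower
    prop_inconclusive: float
    seed: int | None


def bayes_design_analysis(
    d_true: float,
    n: int,
    replications: int = 5000,
    rscale: float = DEFAULT_RSCALE,
    seed: int | None = None,
    bf_upper: float = 3.0,
    bf_lower: float = 1.0 / 3.0,
) -> DesignAnalysisResult:
    """Monte-Carlo Bayes-factor design analysis.

    Each replication draws ``n`` values from Normal(d_true, 1), computes
    the two-sided one-sample JZS Bayes factor, and tallies how often it
    exceeds ``bf_upper`` (evidence for an effect) or falls below
    ``bf_lower`` (evidence for the null).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if replications < 1:
        raise ValueError("replications must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((replications, n)) + d_true
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n))
    n_h1 = n_h0 = 0
    for ti in t:
        bf = jzs_bf10(float(ti), n, rscale)
        if bf > bf_upper:
            n_h1 += 1
        elif bf < bf_lower:
            n_h0 += 1
    return DesignAnalysisResult(
        n=n, d_true=d_true, replications=replications,
        prop_h1=n_h1 / replications, prop_h0=n_h0 / replications,
        prop_inconclusive=(replications - n_h1 - n_h0) / replications,
        seed=seed,
    )


def required_n(
    d_true: float,
    criterion: tuple[str, float],
    n_grid: Iterable[int],
    replications: int = 2000,
    rscale: float = DEFAULT_RSCALE,
    seed: int | None = None,
) -> int | None:
    """Smallest n on a grid meeting an evidence-probability criterion.

    ``criterion`` is ("h1", p) or ("h0", p): require the proportion of
    replications reaching BF10 > 3 (resp. < 1/3) to be at least p.  The
    proportion is assumed monotone in n, so a bisection over the sorted
    grid is used.  Returns None when even the largest grid point fails.
    Each grid point gets its own child seed, so the result does not depend
    on the search path.
    """
    kind, target = criterion
    if kind not in ("h1", "h0"):
        raise ValueError("criterion kind must be 'h1' or 'h0'")
    grid = sorted(set(int(n) for n in n_grid))
    if not grid:
        raise ValueError("empty n grid")
    cache: dict[int, float] = {}

    def prop(n: int) -> float:
        if n not in cache:
            child = np.random.SeedSequence([0 if seed is None else seed, n])
            res = bayes_design_analysis(
                d_true, n, replications, rscale,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            cache[n] = res.prop_h1 if kind == "h1" else res.prop_h0
        return cache[n]

    if prop(grid[-1]) < target:
        return None
    lo, hi = 0, len(grid) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if prop(grid[mid]) >= target:
            hi = mid
        else:
            lo = mid + 1
    return grid[lo]


def power_paired_analytic(
    delta: float, sd: float, n: int, alpha: float = 0.05
) -> float:
    """Exact two-sided power of a paired/one-sample t-test (noncentral t)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    nc = delta / sd * math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    upper = stats.nct.sf(tcrit, n - 1, nc)
    lower = stats.nct.cdf(-tcrit, n - 1, nc)
    # scipy's nct tails underflow to nan at extreme noncentrality
    upper = float(upper) if np.isfinite(upper) else 0.0
    lower = float(lower) if np.isfinite(lower) else 0.0
    return upper + lower


def mc_power_paired(
    delta: float,
    sd: float,
    n: int,
    alpha: float = 0.05,
    replications: int = 10000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo power of a two-sided paired t-test on n differences."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.normal(delta, sd, size=(replications, n))
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    return float(np.mean(np.abs(t) > tcrit))


class MinDetectable(NamedTuple):
    delta: float  # in the units of sd (ms here)
    d: float      # standardized: delta / sd


def min_detectable_difference(
    power_target: float, sd: float, n: int, alpha: float = 0.05
) -> MinDetectable:
    """Smallest paired mean difference detectable at a target power.

    Root-finds delta such that the two-sided noncentral-t power equals
    ``power_target`` (|power - target| < 1e-6 guaranteed by the bracketed
    solver's tolerance).  Scale-equivariant in sd: halving sd halves delta.
    """
    if not 0 < power_target < 1:
        raise ValueError("power_target must lie in (0, 1)")
    hi = sd
    while power_paired_analytic(hi, sd, n, alpha) < power_target:
        hi *= 2
        if hi > 1e6 * sd:
            raise ArithmeticError("failed to bracket the target power")
    delta = optimize.brentq(
        lambda x: power_paired_analytic(x, sd, n, alpha) - power_target,
        0.0, hi, xtol=1e-10 * sd, rtol=8.9e-16,
    )
    return MinDetectable(delta=float(delta), d=float(delta / sd))
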