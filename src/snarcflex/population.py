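"""Population model for the synthetic cohorts.

Each simulated participant carries a latent dRT structure per number range:
an intercept alpha (dRT extrapolated to magnitude 0, in ms), a SNARC slope
beta (ms per magnitude unit; the pair across ranges is bivariate normal
with correlation rho) and a MARC coefficient gamma (ms per parity-contrast
unit).  Reaction times around that structure are ex-Gaussian (normal plus
exponential), the standard right-skewed model for RT data, with occasional
errors, anticipations (< 200 ms) and lapses (> 1500 ms).

Defaults for each experiment are anchored to the group estimates the
analysis recovers on real data of this design: slope means of roughly
(-5.5, -5.8) ms in exp1 and (-10.2, -5.9) ms in exp2, slope SDs of 12-15 ms,
between-range slope correlations of 0.05 (exp1) and 0.34 (exp2), a grand
mean RT near 543 ms (exp1) / 513 ms (exp2), about 5.5% errors and a few
per-mille anticipations plus ~2% slow lapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .stimuli import RANGES


@dataclass(frozen=True)
class RangeEffects:
    """Population mean/SD of the dRT regression per number range."""

    slope_mean: float
    slope_sd: float
    intercept_mean: float
    intercept_sd: float


@dataclass(frozen=True)
class PopulationParams:
    """Generative parameters of a synthetic cohort (ms units throughout)."""

    lower: RangeEffects
    higher: RangeEffects
    slope_correlation: float = 0.05
    marc_mean: float = 0.0
    marc_sd: float = 0.0
    # ex-Gaussian base RT: normal(mu, sigma) + exponential(tau)
    exgauss_mu: float = 448.0
    exgauss_sigma: float = 45.0
    exgauss_tau: float = 95.0
    error_rate: float = 0.055
    p_fast: float = 0.002
    p_slow: float = 0.02
    p_miss: float = 0.0

    def effects(self, range_id: str) -> RangeEffects:
        if range_id == "lower":
            return self.lower
        if range_id == "higher":
            return self.higher
        raise ValueError(f"unknown range_id {range_id!r}")

    def validate(self) -> None:
        for rid in RANGES:
            eff = self.effects(rid)
            if eff.slope_sd < 0:
                raise ValueError(f"{rid}.slope_sd must be >= 0")
            if eff.intercept_sd < 0:
                raise ValueError(f"{rid}.intercept_sd must be >= 0")
        if not -1.0 <= self.slope_correlation <= 1.0:
            raise ValueError("slope_correlation must lie in [-1, 1]")
        if self.marc_sd < 0:
            raise ValueError("marc_sd must be >= 0")
        if self.exgauss_sigma < 0 or self.exgauss_tau < 0:
            raise ValueError("exgauss_sigma and exgauss_tau must be >= 0")
        for name in ("error_rate", "p_fast", "p_slow", "p_miss"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        mean_rt = self.exgauss_mu + self.exgauss_tau
        if not 100.0 < mean_rt < 5000.0:
            raise ValueError(
                f"exgauss_mu + exgauss_tau = {mean_rt:.1f} ms is outside the "
                "plausible RT range (100, 5000)"
            )

    @classmethod
    def reference(cls, experiment_id: str) -> "PopulationParams":
        """Cohort parameters emulating each experiment's group structure."""
        if experiment_id == "exp1":
            return cls(
                lower=RangeEffects(-5.53, 14.66, 11.72, 34.0),
                higher=RangeEffects(-5.84, 12.33, 34.68, 34.0),
                slope_correlation=0.05,
                marc_mean=0.0, marc_sd=0.0,
                exgauss_mu=448.0,
            )
        if experiment_id == "exp2":
            return cls(
                lower=RangeEffects(-10.17, 14.32, 29.93, 34.0),
                higher=RangeEffects(-5.92, 14.32, 33.00, 34.0),
                slope_correlation=0.34,
                marc_mean=10.07, marc_sd=80.0,
                exgauss_mu=418.0,
            )
        raise ValueError(f"unknown experiment_id {experiment_id!r}")

    def with_noise_off(self) -> "PopulationParams":
        """A noiseless copy: deterministic RTs, no errors or contaminants.

        Useful for exact round-trip checks: every computed dRT then equals
        alpha + beta*m + gamma*parity(m) identically.
        """
        return replace(
            self,
            exgauss_sigma=0.0,
            exgauss_tau=0.0,
            error_rate=0.0,
            p_fast=0.0,
            p_slow=0.0,
            p_miss=0.0,
        )


@dataclass(frozen=True)
class ParticipantParams:
    """Realized per-participant parameters plus screening metadata."""

    participant_id: str
    alpha: dict[str, float]
    beta: dict[str, float]
    gamma: float
    exgauss_mu: float
    exgauss_sigma: float
    exgauss_tau: float
    error_rate: float
    p_fast: float
    p_slow: float
    p_miss: float
    block_order_id: int = 1
    age: int = 25
    serious: bool = True
    environment: str = "quiet"
    distractions: str = "none"
    finger_compliance: bool = True


def sample_population(
    params: PopulationParams,
    n_participants: int,
    seed: int | np.random.Generator | None = None,
) -> list[ParticipantParams]:
    """Draw a cohort of participant parameters.

    Slopes per range come from a bivariate normal with the configured
    correlation (constructed from two independent standard normals, so the
    degenerate cases sd = 0 and |rho| = 1 are exact); intercepts and the
    MARC coefficient are independent normals.  Metadata defaults to fully
    compliant values.  Deterministic given the seed.
    """
    params.validate()
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rho = params.slope_correlation
    z1 = rng.standard_normal(n_participants)
    z2 = rng.standard_normal(n_participants)
    zh = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2
    lo, hi = params.lower, params.higher
    beta_lower = lo.slope_mean + lo.slope_sd * z1
    beta_higher = hi.slope_mean + hi.slope_sd * zh
    alpha_lower = rng.normal(lo.intercept_mean, lo.intercept_sd, n_participants)
    alpha_higher = rng.normal(hi.intercept_mean, hi.intercept_sd, n_participants)
    gamma = rng.normal(params.marc_mean, params.marc_sd, n_participants)
    ages = rng.integers(18, 41, n_participants)
    block_orders = rng.integers(1, 5, n_participants)

    cohort = []
    width = max(3, len(str(n_participants)))
    for i in range(n_participants):
        cohort.append(
            ParticipantParams(
                participant_id=f"p{i + 1:0{width}d}",
                alpha={"lower": float(alpha_lower[i]), "higher": float(alpha_higher[i])},
                beta={"lower": float(beta_lower[i]), "higher": float(beta_higher[i])},
                gamma=float(gamma[i]),
                exgauss_mu=params.exgauss_mu,
                exgauss_sigma=params.exgauss_sigma,
                exgauss_tau=params.exgauss_tau,
                error_rate=params.error_rate,
                p_fast=params.p_fast,
                p_slow=params.p_slow,
                p_miss=params.p_miss,
                block_order_id=int(block_orders[i]),
                age=int(ages[i]),
            )
        )
    return cohort
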