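"""Independent validators for the sampler.

Two routes that do not share code with the MCMC implementation:

* a conjugate beta-binomial posterior for the two arm risks, sampled by
  brute-force Monte Carlo to get ``P(effect < t)`` on the risk-ratio or
  odds-ratio scale;
* a closed-form normal approximation on the log-effect scale,
  ``Phi((ln t - log_effect) / se)``.

At the trial's sample sizes the two agree with each other to well under a
percentage point, and the flat-prior sampler must agree with both to
within Monte-Carlo error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats


class OracleError(ValueError):
    """Invalid oracle inputs."""


ORACLE_SEED = 20230421  # default seed for the Monte-Carlo oracle
ORACLE_SAMPLES = 1_000_000  # MC SE <= 0.0005, far below test tolerances


@dataclass(frozen=True)
class BetaPosterior:
    shape_a: float
    shape_b: float

    def __post_init__(self):
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise OracleError("beta shapes must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.shape_a, self.shape_b, size)


@dataclass(frozen=True)
class BetaPosteriorPair:
    treatment: BetaPosterior
    control: BetaPosterior


class OracleProbability(NamedTuple):
    probability: float
    mc_se: float


def beta_binomial_posterior(
    a: int,
    n1: int,
    c: int,
    n2: int,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> BetaPosteriorPair:
    """Conjugate update: ``Beta(prior_a + deaths, prior_b + survivors)`` per arm."""
    if prior_a <= 0 or prior_b <= 0:
        raise OracleError("prior shapes must be positive")
    if not (0 <= a <= n1 and 0 <= c <= n2):
        raise OracleError("counts must satisfy 0 <= deaths <= n")
    return BetaPosteriorPair(
        treatment=BetaPosterior(prior_a + a, prior_b + n1 - a),
        control=BetaPosterior(prior_a + c, prior_b + n2 - c),
    )


def oracle_threshold_probability(
    posterior: BetaPosteriorPair,
    t: float,
    scale: str = "odds-ratio",
    n_samples: int = ORACLE_SAMPLES,
    seed: int = ORACLE_SEED,
) -> OracleProbability:
    """Brute-force ``P(effect < t)`` from independent draws of the two risks."""
    if t <= 0:
        raise OracleError("threshold must be positive")
    rng = np.random.default_rng(seed)
    p1 = posterior.treatment.sample(rng, n_samples)
    p2 = posterior.control.sample(rng, n_samples)
    if scale == "risk-ratio":
        effect = p1 / p2
    elif scale == "odds-ratio":
        effect = (p1 / (1 - p1)) / (p2 / (1 - p2))
    else:
        raise OracleError(f"unknown scale {scale!r}")
    p = float(np.mean(effect < t))
    return OracleProbability(p, math.sqrt(p * (1 - p) / n_samples))


def normal_approx_probability(log_effect: float, se: float, t: float) -> float:
    """``Phi((ln t - log_effect) / se)`` -- normal approximation on the log scale."""
    if se <= 0:
        raise OracleError("se must be positive")
    if t <= 0:
        raise OracleError("threshold must be positive")
    return float(stats.norm.cdf((math.log(t) - log_effect) / se))
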