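"""Posterior evidence summaries: credible intervals, threshold probability
tables, Bayes factors as posterior odds, and Jeffreys evidence labels.

The headline outputs mirror the published evidence spectrum: for each
effect-ratio threshold ``t`` (1.0 down to 0.5), the posterior probability
``P(effect < t)``, the Bayes factor, and its Jeffreys label.  Under the
noninformative (uniform) prior the prior odds of the superiority hypothesis
are even, so the Bayes factor reduces to the posterior odds ``p / (1 - p)``
-- the operationalization that reproduces the published table.  It is
always computed from the unrounded probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np


class EvidenceError(ValueError):
    """Invalid evidence-summary inputs."""


#: Jeffreys bins as (lower bound on BF, label); applied to max(bf, 1/bf).
JEFFREYS_BINS = (
    (100.0, "decisive"),
    (31.6, "very strong"),
    (10.0, "strong"),
    (3.2, "substantial"),
    (1.0, "anecdotal"),
)


class ThresholdProbability(NamedTuple):
    probability: float
    mc_se: float


class LevelOfEvidence(NamedTuple):
    label: str
    direction: str  # "favors hypothesis" or "favors alternative"

    def __str__(self) -> str:
        return self.label if self.direction == "favors hypothesis" else (
            f"{self.label} (favors alternative)"
        )


@dataclass(frozen=True)
class EvidenceRow:
    threshold: float
    probability: float
    mc_se: float
    bayes_factor: float
    loe: LevelOfEvidence


@dataclass
class EvidenceTable:
    endpoint: str
    rows: list[EvidenceRow]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": [r.threshold for r in self.rows],
                "probability": [r.probability for r in self.rows],
                "mc_se": [r.mc_se for r in self.rows],
                "bayes_factor": [r.bayes_factor for r in self.rows],
                "loe": [str(r.loe) for r in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def to_markdown(self) -> str:
        """Grid layout matching the published table: thresholds as columns."""
        header = "| " + " | ".join(
            [f"{self.endpoint}"] + [f"Effect <{r.threshold:g}" for r in self.rows]
        ) + " |"
        sep = "|" + "---|" * (len(self.rows) + 1)
        prob = "| Probability, % | " + " | ".join(
            f"{round(100 * r.probability):d}" for r in self.rows
        ) + " |"
        bf = "| Bayes factor | " + " | ".join(
            format_bayes_factor(r.bayes_factor) for r in self.rows
        ) + " |"
        loe = "| LOE | " + " | ".join(str(r.loe) for r in self.rows) + " |"
        return "\n".join([header, sep, prob, bf, loe])


DEFAULT_THRESHOLDS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)


def credible_interval(
    draws: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """(lower, median, upper) empirical percentiles of the draws.

    Percentiles at ``(1-level)/2``, 0.5 and ``(1+level)/2`` with linear
    interpolation between order statistics.
    """
    v = np.asarray(draws, dtype=float)
    if v.size == 0:
        raise EvidenceError("no draws")
    if v.size < 100:
        warnings.warn(
            f"only {v.size} draws: percentile estimates are imprecise", stacklevel=2
        )
    if not 0.0 < level < 1.0:
        raise EvidenceError("level must lie in (0, 1)")
    lo, med, hi = np.percentile(
        v, [100 * (1 - level) / 2, 50.0, 100 * (1 + level) / 2], method="linear"
    )
    return float(lo), float(med), float(hi)


def threshold_probability(draws: Sequence[float], t: float) -> ThresholdProbability:
    """Fraction of draws strictly below ``t``, with its Monte-Carlo SE."""
    v = np.asarray(draws, dtype=float)
    if v.size == 0:
        raise EvidenceError("no draws")
    if t <= 0:
        raise EvidenceError("threshold must be positive")
    p = float(np.mean(v < t))
    return ThresholdProbability(p, math.sqrt(p * (1 - p) / v.size))


def bayes_factor(probability: float) -> float:
    """Posterior odds ``p / (1 - p)``; ``p = 1`` maps to ``+inf``.

    Must be fed the unrounded probability -- odds are steep near 1, so
    feeding a percent-rounded value distorts the result.
    """
    if not 0.0 <= probability <= 1.0:
        raise EvidenceError("probability must lie in [0, 1]")
    if probability == 1.0:
        return math.inf
    return probability / (1.0 - probability)


def format_bayes_factor(bf: float) -> str:
    """Display form: one decimal; infinite odds render as '>999'."""
    if math.isinf(bf) or bf > 999:
        return ">999"
    return f"{bf:.1f}"


def jeffreys_level(bf: float) -> LevelOfEvidence:
    """Jeffreys evidence label for a Bayes factor.

    Bins on ``[1, 3.2)`` anecdotal, ``[3.2, 10)`` substantial, ``[10, 31.6)``
    strong, ``[31.6, 100)`` very strong, ``>= 100`` decisive.  A BF below 1
    is classified by its reciprocal with the direction flagged as favoring
    the alternative.
    """
    if bf < 0:
        raise EvidenceError("Bayes factor must be nonnegative")
    direction = "favors hypothesis"
    if bf < 1.0:
        direction = "favors alternative"
        bf = math.inf if bf == 0 else 1.0 / bf
    for lower, label in JEFFREYS_BINS:
        if bf >= lower:
            return LevelOfEvidence(label, direction)
    return LevelOfEvidence("anecdotal", direction)


def evidence_table(
    draws: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    endpoint: str = "",
) -> EvidenceTable:
    """One evidence row per threshold (thresholds strictly decreasing)."""
    thresholds = tuple(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise EvidenceError("thresholds must be strictly decreasing")
    if any(t <= 0 for t in thresholds):
        raise EvidenceError("thresholds must be positive")
    rows = []
    for t in thresholds:
        p, se = threshold_probability(draws, t)
        bf = bayes_factor(p)
        rows.append(EvidenceRow(t, p, se, bf, jeffreys_level(bf)))
    return EvidenceTable(endpoint, rows)
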