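"""Shared fixtures: canonical fits of both endpoints, reused across tests.

The expensive MCMC fits (published chain plan: 4 chains, 1000 burn-in,
2000 saved per chain) are session-scoped; the canonical seed 20230421 is
fixed so every numeric check is deterministic.
"""

import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from bayesrct.hierarchical import McmcSettings, fit_model
from bayesrct.trial_data import proppr_counts, stratified_from_counts

CANONICAL_SEED = 20230421


def pooled_table(endpoint):
    a, n1, c, n2 = proppr_counts(endpoint)
    return stratified_from_counts(endpoint, a, n1, c, n2, n_sites=1)


@pytest.fixture(scope="session")
def fit_24h():
    """Flat-prior fit of the 24-hour pooled counts (43/338 vs 58/342)."""
    return fit_model(pooled_table("24h"), mcmc=McmcSettings(seed=CANONICAL_SEED))


@pytest.fixture(scope="session")
def fit_30d():
    """Flat-prior fit of the 30-day pooled counts (76/338 vs 89/342)."""
    return fit_model(pooled_table("30d"), mcmc=McmcSettings(seed=CANONICAL_SEED + 1))


@pytest.fixture(scope="session")
def quick_mcmc():
    """Reduced chain plan for structural tests where precision is irrelevant."""
    return McmcSettings(chains=4, burn_in=300, saved_per_chain=500, seed=CANONICAL_SEED)
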