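"""Shared fixtures: synthetic datasets and fitted models reused across tests."""

import pytest

from ramets import (
    CensusGLMM,
    McmcSettings,
    scenario_field_effects,
    simulate_dataset,
)

#: Short-chain settings for structural unit tests (not for convergence claims).
QUICK = McmcSettings(n_chains=2, n_iter=1200, n_adapt_discard=400, thin=4, seed=7)


@pytest.fixture(scope="session")
def field_like():
    """Default-size field-effects dataset plus its truth record."""
    return simulate_dataset(scenario_field_effects(seed=11))


@pytest.fixture(scope="session")
def field_like_df(field_like):
    return field_like[0]


@pytest.fixture(scope="session")
def field_like_truth(field_like):
    return field_like[1]


@pytest.fixture(scope="session")
def small_df():
    """A 2-block dataset for fast structural checks."""
    df, _ = simulate_dataset(scenario_field_effects(seed=23, n_blocks=2))
    return df


@pytest.fixture(scope="session")
def dry_mass_quickfit(field_like_df):
    """Short-chain Gaussian dry-mass fit shared by structural tests."""
    return CensusGLMM(field_like_df, "dry_mass").fit(QUICK)
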