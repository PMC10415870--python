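import pytest

from nma_stiffness import (
    McmcConfig,
    build_contrasts,
    fit_nma,
    fixture_table1,
    subset_agmd,
)


@pytest.fixture(scope="session")
def table1():
    return fixture_table1()


@pytest.fixture(scope="session")
def contrasts_table1(table1):
    return build_contrasts(table1)


@pytest.fixture(scope="session")
def draws_short(table1):
    """Short-chain fit of the 18-study network, shared across test modules."""
    return fit_nma(
        table1, mcmc=McmcConfig(chains=3, burn_in=2000, samples=8000, seed=11)
    )


@pytest.fixture(scope="session")
def draws_short_agmd(table1):
    return fit_nma(
        subset_agmd(table1),
        mcmc=McmcConfig(chains=3, burn_in=2000, samples=8000, seed=12),
    )
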