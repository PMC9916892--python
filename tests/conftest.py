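import pytest

from varlink.core import GenomicInterval
from varlink.simulate import FixtureSpec, simulate_regulatory_scenario


def gi(chrom, start, end):
    return GenomicInterval(chrom, start, end)


@pytest.fixture(scope="session")
def scenario():
    """The planted regulatory scenario under the default conditions."""
    return simulate_regulatory_scenario(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=1)
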