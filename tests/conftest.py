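import pytest

from cipkfam.simulate import FamilyConfig, generate_family
from cipkfam.structure import load_soybean_catalog


@pytest.fixture(scope="session")
def family_fixture():
    """A small planted family: 10 members (6 intron-poor, 4 intron-rich),
    5 kinase-only and 5 NAF-only decoys, one tandem pair, two segmental
    pairs."""
    return generate_family(FamilyConfig(seed=1))


@pytest.fixture(scope="session")
def family_paths(family_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthetic_family")
    return family_fixture.write(outdir)


@pytest.fixture(scope="session")
def soybean_catalog():
    """The published 52-gene soybean catalog bundled with the package."""
    return load_soybean_catalog()
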