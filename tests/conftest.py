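import numpy as np
import pytest

from platemorph import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def templates():
    return syn.default_templates()


@pytest.fixture(scope="session")
def small_manifest():
    """A compact two-species design: 2 eligible + 1 singleton population each."""
    from platemorph.io import Population, StudyManifest

    pops = [
        Population("Ea-A", "site A", "E_anna", 40.0, -110.0, "sympatric", 2015, 5),
        Population("Ea-B", "site B", "E_anna", 41.0, -111.0, "locally_allopatric", 2015, 4),
        Population("Ea-C", "site C", "E_anna", 42.0, -112.0, "sympatric", 2016, 1),
        Population("Ec-A", "site A", "E_carunculatum", 40.0, -110.0, "sympatric", 2015, 5),
        Population("Ec-B", "site B", "E_carunculatum", 43.0, -113.0, "allopatric", 2016, 4),
        Population("Ec-C", "site C", "E_carunculatum", 44.0, -114.0, "allopatric", 2016, 1),
    ]
    return StudyManifest(pops)


@pytest.fixture(scope="session")
def small_study(small_manifest):
    return syn.generate_study(manifest=small_manifest, master_seed=42)


@pytest.fixture(scope="session")
def full_study():
    """Default synthetic study over the bundled 103-female design."""
    return syn.generate_study(master_seed=7)
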