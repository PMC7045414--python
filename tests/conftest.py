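import pytest

from woodfrac import fixtures
from woodfrac.synthesis import SceneParams, generate_section_scene


@pytest.fixture(scope="session")
def species():
    return fixtures.load_species()


@pytest.fixture(scope="session")
def nutrient_table():
    return fixtures.load_tissue_nutrients()


@pytest.fixture(scope="session")
def trait_table():
    return fixtures.load_trait_table()


@pytest.fixture(scope="session")
def default_scene():
    """One rendered section shared across stereology tests (seed fixed)."""
    return generate_section_scene(SceneParams(), seed=7)
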