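import pytest

from ionphantom.fixtures import load_fixtures
from ionphantom.materials import packaged_material

MATERIAL_NAMES = ("ST", "W", "PMMA", "PS", "Resin", "Epoxy")


@pytest.fixture(scope="session")
def materials():
    return {n: packaged_material(n) for n in MATERIAL_NAMES}


@pytest.fixture(scope="session")
def water(materials):
    return materials["W"]


@pytest.fixture(scope="session")
def fixture_set():
    return load_fixtures()
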