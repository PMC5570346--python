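import pytest

from pgm_paralogs import fixtures


@pytest.fixture(scope="session")
def bundle():
    """The bundled synthetic reference fixtures (built once per session)."""
    return fixtures.reference_bundle()


@pytest.fixture(scope="session")
def pm(bundle):
    return bundle.position_map


@pytest.fixture(scope="session")
def regions_by_label(bundle):
    return {r.label.value: r for r in bundle.regions}
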