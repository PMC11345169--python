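import pytest

from hearscreen import load_paper_fixture, run_pipeline


@pytest.fixture(scope="session")
def paper_config():
    """The bundled 2019-20 parameter set."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def paper_bundle(paper_config):
    """One full pipeline run on the bundled fixture, shared across tests."""
    return run_pipeline(paper_config)
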