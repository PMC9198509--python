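import pytest

from rnaneutralset.energies import load_params


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def backend():
    from rnaneutralset.nnse import ViennaBackend

    return ViennaBackend()
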