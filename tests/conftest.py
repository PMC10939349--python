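import pytest

from archannot import GeneratorConfig, generate_dataset
from archannot import io as aio


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One generated bundle (seed 7) plus its truth manifest, shared
    across tests that only read from it."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = generate_dataset(GeneratorConfig(seed=7), out)
    return aio.load_bundle(out), manifest, out
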