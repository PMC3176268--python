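import pytest

from kefed import fixtures as fx
from kefed.interpreter import default_config
from kefed.model import derive_form


@pytest.fixture(scope="session")
def reference_model():
    return fx.reference_model()


@pytest.fixture(scope="session")
def reference_form(reference_model):
    return derive_form(reference_model)


@pytest.fixture(scope="session")
def demo_atlas():
    return fx.demo_atlas()


@pytest.fixture(scope="session")
def worked_example():
    return fx.worked_example()


@pytest.fixture(scope="session")
def default_scale():
    _, scale = default_config()
    return scale


@pytest.fixture(scope="session")
def default_registry():
    registry, _ = default_config()
    return registry
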