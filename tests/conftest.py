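import pytest

from ph3cohort import default_registry, preset_config

DATA = __import__("pathlib").Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def recommended():
    return preset_config("recommended")


@pytest.fixture(scope="session")
def data_dir():
    return DATA
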