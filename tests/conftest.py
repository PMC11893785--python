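import pytest

from fgf14repeat import default_template


@pytest.fixture(scope="session")
def template():
    return default_template()
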