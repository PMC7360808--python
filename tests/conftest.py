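import pytest

from phasemem import default_config


@pytest.fixture
def cfg():
    """Reference configuration: 12 regular branches, 100 Hz grid, 8.33 Hz SMO."""
    return default_config()


@pytest.fixture
def attention():
    """Default attention burst: 12 spikes at 0, 10, ..., 110 ms."""
    return tuple(range(0, 120, 10))
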