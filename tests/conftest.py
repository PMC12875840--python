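import pytest

from oralcea import table1_defaults


@pytest.fixture(scope="session")
def table1():
    """Canonical published parameter set (session-scoped; treat as read-only)."""
    return table1_defaults()


@pytest.fixture()
def params():
    """A fresh, mutable copy of the canonical parameter set."""
    return table1_defaults()
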