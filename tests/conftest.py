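import pytest

from botanical_rba import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def n_mc():
    """Iteration count for Monte Carlo checks (paper-scale single loop)."""
    return 100_000
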