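import pytest

from intercrop import load_reference_dataset, load_reference_means


@pytest.fixture(scope="session")
def reference_means():
    return load_reference_means("all")


@pytest.fixture(scope="session")
def reference_ds():
    """Reference tables expanded to deterministic pseudo-replicates."""
    return load_reference_dataset("all")
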