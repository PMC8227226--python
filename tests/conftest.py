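import pytest

from mipvolt import SyntheticConfig


@pytest.fixture
def config() -> SyntheticConfig:
    """Default (noisy) study conditions with a fixed seed."""
    return SyntheticConfig(seed=7)


@pytest.fixture
def noiseless(config: SyntheticConfig) -> SyntheticConfig:
    return config.noiseless()
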