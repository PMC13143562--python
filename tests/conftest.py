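import pytest

from dmdtrial import DesignSpec, run_illustration


@pytest.fixture(scope="session")
def trial_design() -> DesignSpec:
    """The running example design: rates 0.7 vs 0.4, alpha 0.025, power 0.9."""
    return DesignSpec(0.7, 0.4)


@pytest.fixture(scope="session")
def example() -> dict:
    """Full output of the bundled worked example (computed once)."""
    return run_illustration()
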