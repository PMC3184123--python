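"""Shared fixtures: one full default-scale scenario recovery per session."""

import pytest

from rasikit.pipeline import recover_scenario

DEFAULT_SEED = 17


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline run on the default synthetic scenario (study conditions).

    Expensive (three libraries of tens of thousands of reads), so shared
    across every test that inspects the end-to-end result.
    """
    return recover_scenario(DEFAULT_SEED)
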