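"""Shared fixtures: small synthetic configurations reused across test modules."""

import pytest

from crgi.simulate import SimulationConfig, generate_screens


@pytest.fixture(scope="session")
def small_config():
    """A compact planted design: 4 CSL + 2 CSV + 20 null pairs, 60 lines."""
    return SimulationConfig(
        seed=123, n_csl=4, n_csv=2, n_null_pairs=20,
        tissues={"lung": 60}, n_patients=150,
    )


@pytest.fixture(scope="session")
def small_screens(small_config):
    return generate_screens(small_config)
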