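import dataclasses

import pytest
from hypothesis import settings

from ovuclock import EngineConfig, ProtocolSpec, default_parameters, integrate, run_protocol

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_small():
    """Calibrated defaults with a reduced ovary (N=100) for fast tests."""
    return default_parameters().replace(ovary={"N": 100})


@pytest.fixture(scope="session")
def eng_fast():
    """150 simulated days at dt=0.02 h with a 40-day transient discard."""
    return EngineConfig(dt=0.02, t_end=150 * 24.0, t_transient=40 * 24.0, seed=1)


@pytest.fixture(scope="session")
def default_run(base_small, eng_fast):
    """One wild-type default-amplitude trial shared across tests."""
    return integrate(base_small, eng_fast)


@pytest.fixture(scope="session")
def amplitude_scan(base_small, eng_fast):
    """Paired-seed amplitude scan spanning regular, irregular and
    no-ovulation regimes (coarse grid, 2 trials)."""
    spec = ProtocolSpec(
        kind="scan", scanned_parameter="A",
        grid=[0.60, 0.66, 0.72, 0.80, 0.90, 1.20, 2.00], trials=2,
    )
    return run_protocol(spec, base_small, eng_fast)


@pytest.fixture()
def eng_short():
    return EngineConfig(dt=0.02, t_end=60 * 24.0, t_transient=20 * 24.0, seed=1)
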