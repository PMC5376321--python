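import numpy as np
import pytest

from ihtwin.config import RunConfig, default_config


@pytest.fixture(scope="session")
def shipped_config() -> RunConfig:
    """The calibrated configuration shipped with the package."""
    return default_config()


@pytest.fixture(scope="session")
def fresh_config() -> RunConfig:
    """An uncalibrated configuration built from dataclass defaults."""
    return RunConfig()


def make_trace(time_s, o2_pct):
    """Bundle (time, O2 %) arrays into the attribute shape metrics expect."""

    class _Trace:
        pass

    t = _Trace()
    t.time_s = np.asarray(time_s, dtype=float)
    t.o2_cage = np.asarray(o2_pct, dtype=float) / 100.0
    return t
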