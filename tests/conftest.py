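import numpy as np
import pytest

from picpool.preprocess import TorqueTrace
from picpool.rates import SmoothedRate
from picpool.simulate import generate_command


@pytest.fixture(scope="session")
def sombrero_cmd():
    return generate_command("sombrero", 10, 30, 3, 10)


@pytest.fixture(scope="session")
def ramp_cmd():
    return generate_command("ramp", 0, 30, 3, 0)


@pytest.fixture
def command_trace():
    """Torque trace that tracks a command exactly (noiseless, in % MVT)."""

    def build(cmd, mvt: float = 40.0) -> TorqueTrace:
        nm = cmd.drive / 100.0 * mvt
        return TorqueTrace(t=cmd.t, torque_raw=nm, torque_filt=nm,
                           torque_pct=cmd.drive.copy(), mvt=mvt, fs=cmd.fs)

    return build


@pytest.fixture
def make_curve():
    """SmoothedRate stub from (t, rate) arrays (interpolating evaluator)."""

    def build(t, rate) -> SmoothedRate:
        return SmoothedRate(t=np.asarray(t, float),
                            rate=np.asarray(rate, float), model_params={})

    return build
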