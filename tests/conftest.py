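import numpy as np
import pytest

from ellcancel import (
    DAPParams,
    DEFAULT_TRANSFER,
    NeuronParams,
    PlasticityParams,
    StimulusSpec,
    simulate,
)

#: coarser step used by unit tests where O(dt) accuracy is not under test
FAST_DT = 5e-5


@pytest.fixture(scope="session")
def transfer():
    return DEFAULT_TRANSFER


@pytest.fixture(scope="session")
def baseline_spikes():
    """30 s of spontaneous (no-AM) activity with the DAP enabled."""
    spec = StimulusSpec(8.0, 0.0, 30.0, "local")
    return simulate(spec, DEFAULT_TRANSFER, dt=FAST_DT, seed=11)


@pytest.fixture(scope="session")
def scaled_plasticity():
    """Desk-scale learning rule: tau_w/20, eta*20 (equilibrium-preserving)."""
    return PlasticityParams().scaled(20.0)
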