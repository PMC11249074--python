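import numpy as np
import pytest

from fibersim import (
    SimulationConfig,
    Trajectory,
    default_table,
    reference_parameters,
    simulate,
)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def ref_params(table):
    return reference_parameters(table)


@pytest.fixture(scope="session")
def ref_config(ref_params):
    return SimulationConfig(params=ref_params)


@pytest.fixture(scope="session")
def ref_traj(ref_config):
    return simulate(ref_config)


def synthetic_trajectory(t, y):
    """Build a minimal Trajectory carrying ``y`` in every pressure slot.

    Synthetic stand-in for exercising extremum detection and classification
    on hand-crafted series; flux and growth columns are zeros.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    zeros = np.zeros_like(y)
    return Trajectory(
        t=t,
        V=np.exp(y / max(np.max(np.abs(y)), 1.0)),
        log_V=y / max(np.max(np.abs(y)), 1.0),
        pi_fiber=y,
        dP=y,
        P_fiber=y,
        F_m=zeros,
        F_p=zeros,
        rgr=zeros,
    )
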