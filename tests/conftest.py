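import numpy as np
import pytest

from motornet import (
    CouplingParams,
    SimulationConfig,
    build_model_space,
    generate_cohort,
    load_table1,
)
from motornet.dcm import default_intrinsic

#: coarse grids used throughout the suite to keep simulations fast:
#: one / two frequency bins per band
FREQS4 = np.array([6.0, 11.0, 22.0, 39.0])
FREQS8 = np.array([5.0, 7.0, 10.0, 13.0, 18.0, 26.0, 35.0, 44.0])

#: restricted cross-frequency pairs for the demo-scale model space
NL_PAIRS = (("beta", "theta"), ("theta", "beta"))


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def model_space():
    return build_model_space(nonlinear_pairs=NL_PAIRS)


@pytest.fixture(scope="session")
def small_cohort(model_space):
    cfg = SimulationConfig(
        frequencies=FREQS4, sample_rate=250.0, n_trials=4, seed=11,
        epoch_window=(-1500.0, 2000.0),
    )
    return generate_cohort(3, 3, cfg, model=model_space[0])


@pytest.fixture()
def stable_params():
    """A tiny hand-built parameter set on the 4-bin grid (stable)."""
    p = CouplingParams(
        frequencies=FREQS4,
        intrinsic=default_intrinsic(FREQS4, decay=5.0),
    )
    F = FREQS4.size
    p.A[("SMA", "cM1")] = 0.5 * np.eye(F)
    p.A[("cM1", "SMA")] = -0.3 * np.eye(F)
    for s in p.source_labels:
        p.C[s] = np.full(F, 100.0)
    return p
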