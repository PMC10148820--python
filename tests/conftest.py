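"""Shared fixtures: reference networks and small synthetic datasets.

Heavy objects (compiled models, equilibria, generated datasets) are cached at
session scope so individual tests stay fast.
"""

import numpy as np
import pytest

from hogpath.calibration import reference_network
from hogpath.network import StrainSpec, TopologyConfig
from hogpath.simulate import InputProtocol, compile_model, equilibrate, run
from hogpath.synthetic import GroundTruth, design_catalogue, generate


@pytest.fixture(scope="session")
def mixed_network():
    return reference_network("mixed")


@pytest.fixture(scope="session")
def mixed_equilibrium(mixed_network):
    model = compile_model(mixed_network)
    y0 = equilibrate(mixed_network, model=model)
    return model, y0


@pytest.fixture(scope="session")
def mixed_step_trajectory(mixed_network, mixed_equilibrium):
    model, y0 = mixed_equilibrium
    tgrid = np.linspace(0.0, 2400.0, 121)
    traj = run(mixed_network, protocol=InputProtocol(kind="step", amplitude=0.4),
               tgrid=tgrid, model=model, y0=y0)
    assert traj.success
    return traj


@pytest.fixture(scope="session")
def small_dataset():
    """Noisy dataset over the two mass-spectrometry series (38 rows)."""
    gt = GroundTruth.reference("mixed", seed=11)
    entries = [e for e in design_catalogue()
               if e.dataset_id in ("ms_hog1pp_wt", "ms_hog1p176_wt")]
    return gt, generate(gt, entries, noise_on=True, seed=11)


@pytest.fixture(scope="session")
def full_dataset():
    gt = GroundTruth.reference("mixed", seed=4)
    return gt, generate(gt, noise_on=True, seed=4)
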