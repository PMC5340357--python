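import numpy as np
import pytest
from hypothesis import settings

import radiolyze as rz

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return rz.GeneratorParams(seed=0)


@pytest.fixture(scope="session")
def double_track(default_params):
    """One low-speed track containing a complete-dissociation event."""
    return rz.generate_track(default_params, 1.0, (7.0, 7.0), seed=42)


@pytest.fixture(scope="session")
def stopped_track(default_params):
    """A low-speed track that stops inside the slab."""
    for seed in range(200):
        traj, log = rz.generate_track(default_params, 1.0, (5.0, 5.0), seed=seed)
        if log.stopped:
            return traj, log
    raise RuntimeError("no stopped track found in 200 seeds")


@pytest.fixture(scope="session")
def mini_ensemble(default_params):
    """20 low-speed tracks with censuses, shared across tests."""
    trajs, logs, censuses = [], [], []
    for traj, log in rz.iter_ensemble_tracks(
        default_params, 1.0, grid=(5, 2), snapshots=2, base_seed=7
    ):
        trajs.append(traj)
        logs.append(log)
        censuses.append(rz.census_vs_projectile(traj))
    return trajs, logs, censuses


def water_frame(box=10.0):
    """A single ideal water monomer centred in a cubic box."""
    pos = np.array(
        [[5.0, 5.0, 5.0], [5.97, 5.0, 5.0], [4.76, 5.92, 5.0]]
    )
    return rz.Frame(
        index=0,
        time=0.0,
        box=[box, box, box],
        symbols=["O", "H", "H"],
        positions=pos,
    )
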