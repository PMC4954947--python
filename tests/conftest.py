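import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from msmbind.featurize import FeatureTrajectory
from msmbind.synthetic import embed_states, preset, sample_ctmc_trajectories


def make_feature_trajectories(system, n_traj, n_frames, seed):
    """Sample a preset and embed every trajectory (deterministic per seed)."""
    dtrajs = sample_ctmc_trajectories(system, n_traj, n_frames, seed=seed)
    seeds = np.random.SeedSequence(seed + 1).spawn(len(dtrajs))
    ftrajs = [
        embed_states(
            dt,
            system.embedding,
            seed=int(np.random.default_rng(ss).integers(2**31 - 1)),
            frame_dt=system.frame_dt,
            source=("synthetic", i),
        )
        for i, (dt, ss) in enumerate(zip(dtrajs, seeds))
    ]
    return dtrajs, ftrajs


@pytest.fixture(scope="session")
def binding5():
    return preset("binding5")


@pytest.fixture(scope="session")
def twostate():
    return preset("twostate")


@pytest.fixture(scope="session")
def binding5_data(binding5):
    """Moderate-size sample of the binding benchmark, shared across tests."""
    return make_feature_trajectories(binding5, n_traj=60, n_frames=2000, seed=11)


@pytest.fixture(scope="session")
def binding5_large(binding5):
    """Full-scale sample used for end-to-end parameter recovery."""
    return make_feature_trajectories(binding5, n_traj=200, n_frames=5000, seed=7)


@pytest.fixture()
def tiny_bundle_dir(tmp_path):
    """Portable two-run bundle: 4 receptor atoms, 2 ligand copies, 1 ion."""
    from msmbind.featurize import TrajectoryBundle, write_bundle

    rng = np.random.default_rng(3)
    n_atoms = 4 + 2 * 2 + 1  # receptor + two 2-atom ligands + ion
    runs = []
    for r in range(2):
        xyz = rng.uniform(0, 30.0, size=(6, n_atoms, 3))
        runs.append((f"run{r}", xyz))
    bundle = TrajectoryBundle(
        runs=runs,
        frame_dt=0.5,
        receptor_atoms=np.arange(4),
        ligand_groups=[np.array([4, 5]), np.array([6, 7])],
        ion_atoms=np.array([8]),
        phosphate_atoms=[np.array([4]), np.array([6])],
    )
    return write_bundle(tmp_path / "bundle", bundle), bundle
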