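"""Shared fixtures: expensive planted-structure trajectories built once."""

import numpy as np
import pytest

from mdbind import (
    PlantedMode,
    gen_gaussian_traj,
    gen_two_state_loop,
    select,
)
from mdbind.synthetic_data import internal_mode_basis

PLANTED_VARIANCES = (0.5, 0.3)   # nm², the planted collective-mode strengths
ISO_NOISE = 0.001                # nm² per coordinate, the noise floor
N_ATOMS = 100
N_FRAMES = 20000
SEED = 20240101


def make_planted_modes(n_atoms: int, variances, seed: int):
    """Random orthonormal *internal* 3N directions with given variances."""
    basis = internal_mode_basis(n_atoms, len(variances), seed)
    return [PlantedMode(direction=basis[:, k], variance=v)
            for k, v in enumerate(variances)]


def make_loop_displacement(n_atoms: int, norm_nm: float, seed: int) -> np.ndarray:
    """A rigid-body-free 3N displacement (survives superposition intact)."""
    d = internal_mode_basis(n_atoms, 1, seed)[:, 0]
    return d * norm_nm


@pytest.fixture(scope="session")
def planted_gaussian():
    """20000-frame, 100-atom trajectory with planted modes (0.5, 0.3 nm²)."""
    modes = make_planted_modes(N_ATOMS, PLANTED_VARIANCES, seed=SEED)
    traj = gen_gaussian_traj(N_ATOMS, modes, ISO_NOISE, N_FRAMES, seed=SEED + 1)
    return traj, modes


@pytest.fixture(scope="session")
def two_state():
    """Two-basin loop trajectory with its ground-truth state labels."""
    n = 30
    d = make_loop_displacement(n, 0.5, seed=SEED + 2)
    traj, labels = gen_two_state_loop(n, d, open_fraction=0.5, n_frames=10000,
                                      jitter=1e-4, seed=SEED + 3)
    return traj, labels


@pytest.fixture(scope="session")
def ca_selection_factory():
    return lambda traj: select(traj, "name CA")
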