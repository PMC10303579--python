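import numpy as np
import pytest

from memepr.mdframes import TrajectoryFrames
from memepr.simulate import (
    FastMotionParams,
    OrderedPowderParams,
    RigidLimitParams,
    simulate_fast_isotropic,
    simulate_ordered_powder,
    simulate_rigid_powder,
)


@pytest.fixture(scope="session")
def clean_fast_spectrum():
    """Noise-free fast-motion spectrum with equal tau targets of 0.2 ns."""
    return simulate_fast_isotropic(
        FastMotionParams(tau_2B_target=2e-10, tau_2C_target=2e-10, noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def clean_ordered_spectrum():
    """Noise-free ordered powder spectrum, S = 0.6, a_o = 14.3 G."""
    return simulate_ordered_powder(
        OrderedPowderParams(S_target=0.6, a_o_target=14.3, noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def clean_rigid_spectrum():
    """Noise-free rigid-limit spectrum, Azz = 34 G."""
    return simulate_rigid_powder(
        RigidLimitParams(A_tensor=(6.0, 6.0, 34.0), noise_sigma=0.0)
    )


@pytest.fixture
def hand_frames():
    """Tiny two-molecule, two-frame trajectory for hand-checkable geometry."""

    def build(coords, names=("C1", "C2", "C3"), resname="CHN", box=None):
        coords = np.asarray(coords, dtype=float)
        n_mol = coords.shape[1] // len(names)
        return TrajectoryFrames(
            mol_ids=np.repeat(np.arange(1, n_mol + 1), len(names)),
            resnames=np.array([resname] * coords.shape[1], dtype=object),
            atom_names=np.array(list(names) * n_mol, dtype=object),
            coords=coords,
            box=box,
        )

    return build
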