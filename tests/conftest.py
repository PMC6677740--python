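import numpy as np
import pytest

from bristlesim.dynamics import GradientParams, ModelParams, SpatialProfile
from bristlesim.geometry import CellLattice, build_disordered_lattice, compute_coupling


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def quiet_params():
    return ModelParams(noise_sigma=0.0)


@pytest.fixture(scope="session")
def flat_gradient():
    """Zero extrinsic signal at all times (period matches a 12-wide box)."""
    zero = SpatialProfile(baseline=0.0, bumps=(), period=12.0)
    return GradientParams(early=zero, late=zero, t_start=0.0, t_end=0.0)


def uniform_gradient(level: float, period: float = 12.0) -> GradientParams:
    prof = SpatialProfile(baseline=level, bumps=(), period=period)
    return GradientParams(early=prof, late=prof, t_start=0.0, t_end=0.0)


@pytest.fixture(scope="session")
def small_lattice():
    return build_disordered_lattice(64, 8.0, 8.0, disorder=0.3, seed=11)


def rosette_lattice() -> CellLattice:
    """Center cell plus 6 hexagonal neighbors at unit distance, in a box
    large enough that periodic images are beyond signaling range."""
    ang = np.linspace(0.0, 2 * np.pi, 7)[:-1]
    pos = np.vstack([[6.0, 6.0], np.c_[6 + np.cos(ang), 6 + np.sin(ang)]])
    pairs = {
        (i, j)
        for i in range(7)
        for j in range(i + 1, 7)
        if np.hypot(*(pos[i] - pos[j])) < 1.1
    }
    return CellLattice(
        positions=pos,
        box_width=12.0,
        box_height=12.0,
        areas=np.full(7, 144.0 / 7),
        neighbor_pairs=frozenset(pairs),
        seed=-1,
    )


@pytest.fixture(scope="session")
def rosette():
    lat = rosette_lattice()
    coup = compute_coupling(lat, signaling_range=1.0, strength=2.0)
    return lat, coup
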