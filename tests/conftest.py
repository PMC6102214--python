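import numpy as np
import pytest

from symring import (
    ToySpec,
    closest_axis_choice,
    make_c2_dimer_template,
    make_toy_monomer,
)

#: dimer COG separation placing the two bundle shells in favourable contact
#: (closest atoms near the Lennard-Jones minimum of the default settings)
DIMER_SEPARATION = 48.0


@pytest.fixture(scope="session")
def helix_monomer():
    """Small ideal-helix CA trace (thin rod along z)."""
    return make_toy_monomer(ToySpec(n_residues=12, shape="helix"))


@pytest.fixture(scope="session")
def bundle_monomer():
    """30-residue CA shell with a globular-subunit footprint (~40 A across)."""
    return make_toy_monomer(ToySpec(n_residues=30, shape="helical_bundle"))


@pytest.fixture(scope="session")
def c2_dimer(bundle_monomer):
    """Exactly C2-symmetric 60-atom dimer (C2 axis = z, through the origin)."""
    return make_c2_dimer_template(bundle_monomer, separation=DIMER_SEPARATION)


@pytest.fixture(scope="session")
def c2_axis_choice(c2_dimer):
    """Principal-axis choice whose axis coincides with the dimer's C2 (z) axis."""
    return closest_axis_choice(c2_dimer, direction=(0.0, 0.0, 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
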