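import numpy as np
import pytest

import ptmscope as pt
from ptmscope.synthetic import _planted_ca_modes


@pytest.fixture(scope="session")
def toy_dimer():
    return pt.make_toy_dimer(pt.ToySpec(n_res_per_chain=9, separation=2.0, seed=1))


@pytest.fixture(scope="session")
def far_dimer():
    return pt.make_toy_dimer(pt.ToySpec(n_res_per_chain=9, separation=100.0, seed=1))


@pytest.fixture(scope="session")
def slab_pair():
    return pt.make_slab_pair(n_side=12, gap=3.0, spacing=2.0)


@pytest.fixture(scope="session")
def ca_mode(toy_dimer):
    """One planted non-rigid unit Cα displacement mode and its indices."""
    rng = np.random.default_rng(11)
    modes, ca = _planted_ca_modes(toy_dimer, 1, rng)
    return modes[0], ca


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
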