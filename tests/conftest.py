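import numpy as np
import pytest

from rescaffold.fixtures import (ToyScaffoldParams, make_toy_scaffold,
                                 default_triad)
from rescaffold.motif_scaffold import MotifSpec


@pytest.fixture(scope="session")
def scaffold40():
    """40-residue toy scaffold with an ideal triad at (3.0, 2.8) Å."""
    return make_toy_scaffold(ToyScaffoldParams(n_residues=40, seed=1))


@pytest.fixture(scope="session")
def triad40(scaffold40):
    return default_triad(scaffold40)


@pytest.fixture(scope="session")
def motif_spec40():
    """Three kept segments on the 40-residue scaffold, one triad residue each.

    Triad residues of the generator sit at resnums 7, 21, 34 for n = 40.
    """
    return MotifSpec(
        segments=[("A", 5, 10), ("A", 18, 24), ("A", 31, 36)],
        catalytic=[("nucleophile", "A", 7), ("base", "A", 21),
                   ("acid", "A", 34)],
    )


@pytest.fixture(scope="session")
def allres_spec40():
    """Whole-chain spec: motif RMSD over it equals full backbone RMSD."""
    return MotifSpec(
        segments=[("A", 1, 40)],
        catalytic=[("nucleophile", "A", 7), ("base", "A", 21),
                   ("acid", "A", 34)],
    )


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def rigidly_move(model, rng):
    """Apply one random proper rigid motion to every atom of a model copy."""
    from rescaffold.fixtures import _copy_model
    R = random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    new = _copy_model(model)
    for res in new.residues:
        for a in res.atoms:
            a.coords = R @ a.coords + t
    return new
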