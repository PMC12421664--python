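import numpy as np
import pytest

from ledkit import Atom, Geometry


def make_water(origin, jitter=None):
    """One O-H-H unit (O-H ~ 0.96 Å) at ``origin``."""
    base = np.array([[0.0, 0.0, 0.0], [0.76, 0.59, 0.0], [-0.76, 0.59, 0.0]])
    if jitter is not None:
        base = base + jitter
    return [Atom(el, xyz + np.asarray(origin, float)) for el, xyz in zip(("O", "H", "H"), base)]


@pytest.fixture
def water_hexamer() -> Geometry:
    """Six water molecules with intermolecular O···O >= 2.7 Å."""
    atoms = []
    for k in range(6):
        atoms.extend(make_water([3.0 * (k % 3), 3.2 * (k // 3), 0.0]))
    return Geometry(atoms=atoms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
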