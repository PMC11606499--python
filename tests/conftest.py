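import numpy as np
import pytest

from bmcshell.shellgen import SyntheticShellSpec, generate_shell
from bmcshell.structio import AtomRecord


def make_atom(chain, resname, resnum, atom, element, x, y, z):
    return AtomRecord(chain=chain, resname=resname, resnum=resnum, atom=atom,
                      element=element, position=np.array([x, y, z], float))


@pytest.fixture(scope="session")
def t9_shell():
    """Noise-free synthetic T=9 shell (80 hexamers + 12 pentamers)."""
    return generate_shell(SyntheticShellSpec(3, 0))


@pytest.fixture(scope="session")
def t1_shell():
    """Bare pentamer icosahedron (12 pentamers, 60 chains)."""
    return generate_shell(SyntheticShellSpec(1, 0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
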