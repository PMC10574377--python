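import numpy as np
import pytest

from gmri import Architecture, TrainingSet, smiles_to_dag

SMALL_ALPHABET = ("C", "N", "O", "F", "S", "Cl")

#: a structurally varied hand-picked molecule set (rings, stereo, leaves)
FIXTURE_SMILES = [
    "CCO",
    "CC(C)=O",
    "C/C=C\\C",
    "C/C=C/C",
    "CC1OC1C",
    "C[C@H]1O[C@@H]1C",
    "C[C@H]1O[C@H]1C",
    "c1ccccc1",
    "CC(F)(F)C#N",
    "CCSC",
    "ClCCCl",
    "OCC(O)CO",
]


@pytest.fixture(scope="session")
def small_arch():
    return Architecture(n_hidden=3, atom_alphabet=SMALL_ALPHABET)


@pytest.fixture(scope="session")
def fixture_dags():
    return [smiles_to_dag(s, alphabet=SMALL_ALPHABET) for s in FIXTURE_SMILES]


@pytest.fixture(scope="session")
def linear_single_atom_tset():
    """Single-atom molecules: the graph machine degenerates to linear
    regression on the label indicators, the regime where the PRESS/LOO
    identity is exact.  Every atom type appears several times so each
    leave-one-out prediction is unique even under rank deficiency."""
    arch = Architecture(n_hidden=0, atom_alphabet=("C", "N", "O", "S", "Cl"))
    rng = np.random.default_rng(42)
    smiles = (["C", "N", "O", "S", "Cl"] * 6)[:30]
    dags = [smiles_to_dag(s, alphabet=arch.atom_alphabet) for s in smiles]
    y = 1.4 + 0.05 * rng.standard_normal(len(dags))
    return TrainingSet(dags, y, arch)


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test generator (stable across processes)."""
    import zlib

    return np.random.default_rng(zlib.crc32(name.encode()) % 2**31)
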