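import numpy as np
import pytest

from xaqsar.molgraph import parse_molecule
from xaqsar.synthetic import MotifRecipe, gen_motif_molecule


@pytest.fixture(scope="session")
def benzene():
    return parse_molecule("c1ccccc1")


@pytest.fixture(scope="session")
def pyridine():
    return parse_molecule("c1ccncc1")


@pytest.fixture(scope="session")
def acetamide():
    return parse_molecule("CC(N)=O")


def _random_recipes(rng):
    recipes = []
    if rng.random() < 0.7:
        recipes.append(MotifRecipe("Cl_amideN_at_k", k=int(rng.integers(2, 8))))
    if rng.random() < 0.7:
        recipes.append(MotifRecipe("sp2O_sp3O_at_k", k=int(rng.integers(3, 9))))
    if rng.random() < 0.5:
        recipes.append(MotifRecipe("sp2N_sp3O_at_k", k=int(rng.integers(3, 11))))
    if rng.random() < 0.5:
        recipes.append(MotifRecipe("sp2C_sp2O_at_k", k=int(rng.integers(3, 11))))
    if rng.random() < 0.6:
        recipes.append(MotifRecipe("aroN_ring", count=int(rng.integers(1, 3))))
    if rng.random() < 0.6:
        recipes.append(MotifRecipe("ring_with_positive_C", count=int(rng.integers(1, 3))))
    return recipes


@pytest.fixture(scope="session")
def synthetic_batch():
    """200 varied synthetic molecules shared by the descriptor-engine checks."""
    rng = np.random.default_rng(2024)
    mols = []
    for _ in range(200):
        smiles = gen_motif_molecule(
            _random_recipes(rng), seed=int(rng.integers(0, 2**31 - 1))
        )
        mols.append(parse_molecule(smiles))
    return mols
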