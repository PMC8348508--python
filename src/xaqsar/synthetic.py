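"""Synthetic molecules with controlled motifs and planted linear tables.

Molecule generation works by template assembly: each motif is a small
functional-group template whose characteristic atom pair sits at an exact
bond distance by construction, and templates are joined through long
saturated linkers (>= 10 CH2 units) so that cross-template distances can
never create or destroy a motif at the descriptor ranges used here (k <= 11).
This guarantees motif fidelity without rejection sampling.

Motifs:

- ``Cl_amideN_at_k``: chlorine with an amide nitrogen exactly k bonds away.
- ``sp2O_sp3O_at_k``: carbonyl (sp2) oxygen with an ether (sp3) oxygen
  exactly k bonds away (k >= 3; at k = 2 the ester oxygen is perceived sp2).
- ``sp2N_sp3O_at_k``: guanidine-like sp2 nitrogen with an ether oxygen
  exactly k bonds away.
- ``sp2C_sp2O_at_k``: sulfinyl (sp2) oxygen whose nearest sp2 carbon (a
  vinyl terminus) is exactly k bonds away — a carbonyl oxygen cannot serve
  here because its own carbon is sp2 at distance 1.
- ``aroN_ring``: a pyridine ring (one aromatic nitrogen).
- ``ring_with_positive_C``: a tetrahydrofuran ring, whose carbons adjacent
  to oxygen carry positive Gasteiger charge.

Planted descriptor tables emulate the modeling matrix: small non-negative
integer counts (Poisson-like) for frequency descriptors, bounded floats for
charge sums, and a sparse linear response y = b0 + sum(b_i x_i) + noise over
a pool of independent decoy columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .descriptors import DescriptorSpec, named_descriptor_set, proximity_value, compute_matrix
from .exceptions import GenerationError
from .molgraph import MolGraph, classify_atoms, parse_molecule

_MIN_LINKER = 10  # CH2 units; keeps every cross-template distance > 11 bonds


@dataclass(frozen=True)
class MotifRecipe:
    motif: str
    k: int | None = None
    count: int = 1


@dataclass
class PlantedTableSpec:
    """Study conditions for the planted-response recovery experiments."""

    n: int = 300
    p_decoy: int = 194
    sigma: float = 0.3
    beta0: float = 6.176
    betas: tuple[float, ...] = (1.513, 0.519, 1.197, -1.018, -1.091, -0.9)
    seed: int = 0


def _template(recipe: MotifRecipe, rng: np.random.Generator) -> tuple[str, int, int]:
    """(SMILES, attach-in index, attach-out index) for one motif occurrence.

    Aromatic templates need two distinct attachment carbons: an aromatic
    carbon bearing two substituents cannot be kekulized.
    """
    motif, k = recipe.motif, recipe.k
    if motif == "Cl_amideN_at_k":
        if k is None or k < 2:
            raise GenerationError(f"{motif} needs k >= 2")
        return "Cl" + "C" * (k - 1) + "NC(C)=O", k + 2, k + 2  # amide methyl
    if motif == "sp2O_sp3O_at_k":
        if k is None or k < 3:
            raise GenerationError(f"{motif} needs k >= 3")
        return "CC(=O)" + "C" * (k - 2) + "OC", 0, 0  # acetyl methyl
    if motif == "sp2N_sp3O_at_k":
        # k >= 3: at k = 2 the oxygen sits on the conjugated carbon and is
        # perceived sp2 (carbamimidate), so no sp3 oxygen would be planted
        if k is None or k < 3:
            raise GenerationError(f"{motif} needs k >= 3")
        return "NC(=N)" + "C" * (k - 2) + "OC", k + 2, k + 2  # O-methyl
    if motif == "sp2C_sp2O_at_k":
        if k is None or k < 3:
            raise GenerationError(f"{motif} needs k >= 3")
        return "C=C" + "C" * (k - 2) + "S(C)=O", k + 1, k + 1  # S-methyl
    if motif == "aroN_ring":
        return "c1ccncc1", 0, 1
    if motif == "ring_with_positive_C":
        # tetrahydrofuran or 1,3-dioxolane; both carry positively charged
        # ring carbons, the dioxolane about three times the charge sum
        if rng.random() < 0.5:
            return "C1CCOC1", 0, 1
        return "C1OCOC1", 2, 4  # attach on the CH2 carbons
    raise GenerationError(f"unknown motif {motif!r}")


def gen_motif_molecule(recipes: Sequence[MotifRecipe], seed: int = 0) -> str:
    """Assemble one valid SMILES realizing every requested motif.

    The generated molecule is verified: each motif's descriptor is recomputed
    and must reach the requested count, otherwise a GenerationError is raised.
    """
    rng = np.random.default_rng(seed)
    fragments: list[tuple[str, int, int]] = []
    for recipe in recipes:
        for _ in range(recipe.count):
            fragments.append(_template(recipe, rng))
    if not fragments:
        return "C" * int(6 + rng.integers(0, 5))  # plain alkane

    smiles0, _, out0 = fragments[0]
    base = Chem.RWMol(Chem.MolFromSmiles(smiles0))
    prev_out = out0
    for smiles_i, attach_in, attach_out in fragments[1:]:
        frag = Chem.MolFromSmiles(smiles_i)
        offset = base.GetNumAtoms()
        base = Chem.RWMol(Chem.CombineMols(base, frag))
        linker_len = int(_MIN_LINKER + rng.integers(0, 3))
        chain = [base.AddAtom(Chem.Atom(6)) for _ in range(linker_len)]
        path = [prev_out, *chain, offset + attach_in]
        for a, b in zip(path, path[1:]):
            base.AddBond(a, b, Chem.BondType.SINGLE)
        prev_out = offset + attach_out
    Chem.SanitizeMol(base)
    smiles = Chem.MolToSmiles(base)

    _verify_motifs(smiles, recipes)
    return smiles


_MOTIF_CLASSES = {
    "Cl_amideN_at_k": ("Cl", "amideN"),
    "sp2O_sp3O_at_k": ("sp2O", "sp3O"),
    "sp2N_sp3O_at_k": ("sp2N", "sp3O"),
    "sp2C_sp2O_at_k": ("sp2C", "sp2O"),
}


def _verify_motifs(smiles: str, recipes: Sequence[MotifRecipe]) -> None:
    mol = parse_molecule(smiles)
    wanted: dict[tuple, int] = {}
    for recipe in recipes:
        key = (recipe.motif, recipe.k)
        wanted[key] = wanted.get(key, 0) + recipe.count
    for (motif, k), count in wanted.items():
        if motif in _MOTIF_CLASSES:
            source, target = _MOTIF_CLASSES[motif]
            spec = DescriptorSpec(
                f"check_{motif}_{k}", "proximity", target, source, k, "exactly_k_excl"
            )
            realized = proximity_value(mol, spec)
        elif motif == "aroN_ring":
            realized = len(classify_atoms(mol, "aroN"))
        else:  # ring_with_positive_C
            realized = len(classify_atoms(mol, "ringCplus"))
        if realized < count:
            raise GenerationError(
                f"motif {motif} (k={k}) requested {count}, realized {realized} "
                f"in {smiles}"
            )


# --- synthetic study set ------------------------------------------------------


def _random_recipes(rng: np.random.Generator) -> list[MotifRecipe]:
    recipes: list[MotifRecipe] = []
    n_pyridine = int(rng.integers(0, 3))
    if n_pyridine:
        recipes.append(MotifRecipe("aroN_ring", count=n_pyridine))
    n_thf = int(rng.integers(0, 3))
    if n_thf:
        recipes.append(MotifRecipe("ring_with_positive_C", count=n_thf))
    if rng.random() < 0.6:
        k = 5 if rng.random() < 0.6 else int(rng.choice([3, 4, 6, 7]))
        recipes.append(MotifRecipe("Cl_amideN_at_k", k=k))
    if rng.random() < 0.6:
        k = 6 if rng.random() < 0.6 else int(rng.choice([4, 5, 7, 8]))
        recipes.append(MotifRecipe("sp2O_sp3O_at_k", k=k))
    if rng.random() < 0.5:
        k = 9 if rng.random() < 0.6 else int(rng.choice([7, 8, 10]))
        recipes.append(MotifRecipe("sp2N_sp3O_at_k", k=k))
    if rng.random() < 0.5:
        k = 8 if rng.random() < 0.6 else int(rng.choice([6, 7, 9, 10]))
        recipes.append(MotifRecipe("sp2C_sp2O_at_k", k=k))
    return recipes


def gen_study_set(
    n_molecules: int = 120, seed: int = 0, noise_sd: float = 0.3
) -> pd.DataFrame:
    """A synthetic inhibitor library whose activities follow the published
    six-descriptor structure-activity relationship plus Gaussian noise.

    Returns a frame with columns id, smiles, ki_nM, pki_true. Activities are
    generated as pKi = published model applied to the molecule's computed
    descriptors + N(0, noise_sd), then back-transformed to Ki in nM.
    """
    from .validation import predict, published_model

    rng = np.random.default_rng(seed)
    smiles_list = []
    for i in range(n_molecules):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        smiles_list.append(gen_motif_molecule(_random_recipes(rng), seed=sub_seed))
    mols = [parse_molecule(s) for s in smiles_list]
    ids = [f"SYN{i + 1:04d}" for i in range(n_molecules)]
    X = compute_matrix(mols, named_descriptor_set(), ids=ids)
    model = published_model()
    pki = predict(model, X) + rng.normal(0.0, noise_sd, size=n_molecules)
    ki_nM = 10.0 ** (9.0 - pki)
    return pd.DataFrame(
        {"id": ids, "smiles": smiles_list, "ki_nM": ki_nM, "pki_true": pki}
    )


def write_study_files(frame: pd.DataFrame, csv_path, smi_path=None) -> None:
    """Emit the activity CSV (and optionally a .smi file) in the pipeline's
    input dialect."""
    frame[["id", "smiles", "ki_nM"]].to_csv(csv_path, index=False)
    if smi_path is not None:
        with open(smi_path, "w") as handle:
            for _, row in frame.iterrows():
                handle.write(f"{row['smiles']} {row['id']}\n")


# --- planted linear tables ----------------------------------------------------


def gen_planted_table(
    spec: PlantedTableSpec,
) -> tuple[pd.DataFrame, pd.Series, list[str], np.ndarray]:
    """Descriptor table with a sparse planted linear response.

    Returns (X, y, true column names, beta) where beta = (b0, b1..bp). The
    first informative column is continuous on [0, 1.5] (charge-sum-like); the
    rest are Poisson counts. Decoys mimic both column types and are
    independent of y.
    """
    p_true = len(spec.betas)
    if spec.n <= p_true + 2:
        raise ValueError("n must exceed the number of informative columns + 2")
    rng = np.random.default_rng(spec.seed)

    def column(kind: str) -> np.ndarray:
        if kind == "charge":
            return rng.uniform(0.0, 1.5, size=spec.n)
        return rng.poisson(1.0, size=spec.n).astype(float)

    true_names = [f"true_{i + 1}" for i in range(p_true)]
    true_cols = {
        name: column("charge" if i == 0 else "count")
        for i, name in enumerate(true_names)
    }
    decoy_names = [f"decoy_{i + 1}" for i in range(spec.p_decoy)]
    decoy_cols = {
        name: column("charge" if i % 2 else "count")
        for i, name in enumerate(decoy_names)
    }
    X = pd.DataFrame({**true_cols, **decoy_cols})
    X = X[rng.permutation(X.columns.to_list())]  # shuffle column order
    y_values = spec.beta0 + sum(
        beta * true_cols[name] for beta, name in zip(spec.betas, true_names)
    )
    if spec.sigma > 0:
        y_values = y_values + rng.normal(0.0, spec.sigma, size=spec.n)
    y = pd.Series(np.asarray(y_values, float), name="pki")
    beta = np.concatenate([[spec.beta0], list(spec.betas)])
    return X, y, true_names, beta


def write_planted_files(X, y, true_names, beta, spec, csv_path, truth_path) -> None:
    import json

    table = X.copy()
    table.insert(0, "pki", y)
    table.to_csv(csv_path, index=False)
    with open(truth_path, "w") as handle:
        json.dump(
            {
                "beta0": beta[0],
                "betas": list(beta[1:]),
                "true_names": list(true_names),
                "sigma": spec.sigma,
                "seed": spec.seed,
                "n": spec.n,
                "p_decoy": spec.p_decoy,
            },
            handle,
            indent=2,
        )
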