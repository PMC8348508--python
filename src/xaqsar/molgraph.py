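"""Annotated hydrogen-suppressed molecular graphs and dataset curation.

A :class:`MolGraph` is the in-memory molecule representation used by the
descriptor engine: per-atom element, aromaticity, hybridization, ring
membership, formal and partial charge, plus the all-pairs topological
distance matrix (bond counts along shortest heavy-atom paths). Hydrogens are
implicit and never appear as graph vertices.

Atom classes (``ringC``, ``aroN``, ``amideN``, ...) are named predicates over
annotated atoms; they are the building blocks of the proximity descriptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges

from .exceptions import ConfigurationError, CurationError, MoleculeParseError

#: Elements regarded as "organic" during curation; anything else is treated
#: as a metal (or metalloid outside medicinal-chemistry scope) and the
#: molecule is dropped.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

_HYBRIDIZATION = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a molecular graph."""

    symbol: str
    aromatic: bool
    hybridization: str  # "sp" | "sp2" | "sp3" | "other"
    in_ring: bool
    formal_charge: int
    partial_charge: float


@dataclass
class MolGraph:
    """Hydrogen-suppressed molecular graph with annotations.

    ``dist[i, j]`` is the number of bonds on the shortest path between heavy
    atoms *i* and *j* (``inf`` for atoms in different fragments).
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]  # (i, j, bond order)
    dist: np.ndarray
    canonical_smiles: str

    _adjacency: dict[int, list[tuple[int, float]]] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        """Neighbours of atom *i* as (index, bond order) pairs."""
        if self._adjacency is None:
            adj: dict[int, list[tuple[int, float]]] = {
                k: [] for k in range(self.n_atoms)
            }
            for a, b, order in self.bonds:
                adj[a].append((b, order))
                adj[b].append((a, order))
            self._adjacency = adj
        return self._adjacency[i]


def parse_molecule(
    smiles: str, mol_id: str | None = None, charge_scheme: str = "gasteiger"
) -> MolGraph:
    """Parse a SMILES string into a fully annotated :class:`MolGraph`.

    Aromaticity, ring membership and hybridization come from the toolkit's
    perception; aromatic atoms are mapped to sp2. Partial charges use the
    Gasteiger-Marsili scheme by default (``charge_scheme="gasteiger"`` is
    currently the only implemented option; the parameter exists so the
    charge model is an explicit, recorded choice).
    """
    if charge_scheme != "gasteiger":
        raise ConfigurationError(f"unknown partial-charge scheme: {charge_scheme!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" (id={mol_id})" if mol_id is not None else ""
        raise MoleculeParseError(f"unparseable SMILES{label}: {smiles!r}")
    ComputeGasteigerCharges(mol)

    atoms: list[Atom] = []
    for a in mol.GetAtoms():
        charge = float(a.GetDoubleProp("_GasteigerCharge"))
        if not math.isfinite(charge):
            charge = 0.0
        if a.GetIsAromatic():
            hyb = "sp2"
        else:
            hyb = _HYBRIDIZATION.get(a.GetHybridization(), "other")
        atoms.append(
            Atom(
                symbol=a.GetSymbol(),
                aromatic=a.GetIsAromatic(),
                hybridization=hyb,
                in_ring=a.IsInRing(),
                formal_charge=a.GetFormalCharge(),
                partial_charge=charge,
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    dist = np.array(Chem.GetDistanceMatrix(mol), dtype=float, copy=True)
    dist[dist > 1e7] = np.inf  # toolkit sentinel for disconnected pairs
    return MolGraph(
        atoms=atoms,
        bonds=bonds,
        dist=dist,
        canonical_smiles=Chem.MolToSmiles(mol),
    )


# --- atom classes -----------------------------------------------------------


def _is_amide_n(mol: MolGraph, i: int) -> bool:
    # N single-bonded to a carbon bearing a double-bonded O
    if mol.atoms[i].symbol != "N":
        return False
    for j, order in mol.neighbors(i):
        if order == 1.0 and mol.atoms[j].symbol == "C":
            for k, order2 in mol.neighbors(j):
                if k != i and order2 == 2.0 and mol.atoms[k].symbol == "O":
                    return True
    return False


ATOM_CLASSES: Mapping[str, Callable[[MolGraph, int], bool]] = {
    "ringC": lambda m, i: m.atoms[i].symbol == "C" and m.atoms[i].in_ring,
    "Cplus": lambda m, i: m.atoms[i].symbol == "C" and m.atoms[i].partial_charge > 0,
    "ringCplus": lambda m, i: (
        m.atoms[i].symbol == "C"
        and m.atoms[i].in_ring
        and m.atoms[i].partial_charge > 0
    ),
    "aroC": lambda m, i: m.atoms[i].symbol == "C" and m.atoms[i].aromatic,
    "aroCplus": lambda m, i: (
        m.atoms[i].symbol == "C" and m.atoms[i].aromatic and m.atoms[i].partial_charge > 0
    ),
    "aroN": lambda m, i: m.atoms[i].symbol == "N" and m.atoms[i].aromatic,
    "sp2C": lambda m, i: m.atoms[i].symbol == "C" and m.atoms[i].hybridization == "sp2",
    "sp3O": lambda m, i: m.atoms[i].symbol == "O" and m.atoms[i].hybridization == "sp3",
    "sp2O": lambda m, i: m.atoms[i].symbol == "O" and m.atoms[i].hybridization == "sp2",
    "sp2N": lambda m, i: m.atoms[i].symbol == "N" and m.atoms[i].hybridization == "sp2",
    "amideN": _is_amide_n,
    "Cl": lambda m, i: m.atoms[i].symbol == "Cl",
}


def classify_atoms(mol: MolGraph, cls: str) -> frozenset[int]:
    """Indices of atoms in *mol* that satisfy the named atom class."""
    try:
        predicate = ATOM_CLASSES[cls]
    except KeyError:
        raise ConfigurationError(
            f"unknown atom class {cls!r}; known: {sorted(ATOM_CLASSES)}"
        ) from None
    return frozenset(i for i in range(mol.n_atoms) if predicate(mol, i))


# --- activity records and curation ------------------------------------------


@dataclass(frozen=True)
class ActivityRecord:
    """A curated molecule: canonical SMILES plus measured Ki and its pKi."""

    id: str
    smiles: str
    ki_nM: float
    pki: float


def to_pki(ki_nM: float) -> float:
    """Negative log molar transform: pKi = -log10(Ki[nM] * 1e-9)."""
    ki = float(ki_nM)
    if not math.isfinite(ki) or ki <= 0:
        raise ValueError(f"Ki must be a positive finite value, got {ki_nM!r}")
    return 9.0 - math.log10(ki)


def _coerce_ki(value) -> float | None:
    """Parse a Ki field; ``None`` marks an ambiguous/qualified value."""
    if value is None:
        return None
    if isinstance(value, str):
        text = value.strip().replace(",", "")
        if not text or any(q in text for q in ("<", ">", "~", "≥", "≤")):
            return None
        try:
            value = float(text)
        except ValueError:
            return None
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        return None
    return value


def curate(records: Iterable) -> list[ActivityRecord]:
    """Apply the curation rules and return surviving :class:`ActivityRecord`s.

    Rules, in order: drop entries with missing/qualified/non-positive Ki;
    drop unparseable SMILES; keep the largest fragment (salt stripping, ties
    broken by first fragment); drop molecules containing non-organic
    elements; deduplicate by canonical SMILES keeping the first occurrence.
    """
    survivors: list[ActivityRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(records):
        if isinstance(rec, ActivityRecord):
            rec_id, smiles, ki_raw = rec.id, rec.smiles, rec.ki_nM
        elif isinstance(rec, Mapping):
            rec_id = str(rec.get("id", idx))
            smiles = rec.get("smiles", "")
            ki_raw = rec.get("ki_nM", rec.get("ki"))
        else:  # (id, smiles, ki) tuples
            rec_id, smiles, ki_raw = str(rec[0]), rec[1], rec[2]
        ki = _coerce_ki(ki_raw)
        if ki is None:
            continue
        mol = Chem.MolFromSmiles(str(smiles))
        if mol is None:
            continue
        frags = Chem.GetMolFrags(mol, asMols=True)
        frag = max(frags, key=lambda f: f.GetNumHeavyAtoms())
        if any(a.GetSymbol() not in ORGANIC_ELEMENTS for a in frag.GetAtoms()):
            continue
        canonical = Chem.MolToSmiles(frag)
        if canonical in seen:
            continue
        seen.add(canonical)
        survivors.append(
            ActivityRecord(id=rec_id, smiles=canonical, ki_nM=ki, pki=to_pki(ki))
        )
    if not survivors:
        raise CurationError("curation removed every record")
    return survivors


# --- I/O ---------------------------------------------------------------------


def read_activity_csv(path) -> list[dict]:
    """Read ``id,smiles,ki_nM`` CSV (header required) into raw record dicts."""
    from .exceptions import SchemaError

    frame = pd.read_csv(path, dtype={"id": str, "smiles": str, "ki_nM": str})
    missing = {"id", "smiles", "ki_nM"} - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return frame.to_dict(orient="records")


def read_smi(path) -> list[dict]:
    """Read a whitespace-separated ``smiles id`` file (no activities)."""
    out = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else str(line_no)
            out.append({"id": mol_id, "smiles": smiles, "ki_nM": None})
    return out


def write_curated_csv(records: Sequence[ActivityRecord], path) -> None:
    """Write curated records as ``id,canonical_smiles,ki_nM,pki`` (pKi to 3 dp)."""
    frame = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "canonical_smiles": [r.smiles for r in records],
            "ki_nM": [r.ki_nM for r in records],
            "pki": [round(r.pki, 3) for r in records],
        }
    )
    frame.to_csv(path, index=False)
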