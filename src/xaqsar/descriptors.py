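"""Topological proximity descriptors over annotated molecular graphs.

The engine evaluates three kinds of descriptor:

``count``
    Number of atoms in a target atom class (e.g. ``ringC``).
``charge_sum``
    Sum of partial charges over a target class (e.g. ``ringCplus_sumpc``).
``proximity``
    Counts over topological bond distances between a source class A and a
    target class B. For each target atom b, let d(b) be the minimum bond
    distance from b to any source atom (excluding b itself when it belongs
    to both classes). Three counting modes:

    - ``exactly_k_excl``: targets with d(b) == k. A target that also sits
      within 1..k-1 bonds of another source atom has d(b) < k and is thereby
      excluded — the "frequency at exactly k bonds" semantics.
    - ``within_le_k``: targets with 1 <= d(b) <= k.
    - ``pairs_le_k``: all (source, target) pairs with 1 <= dist <= k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, PipelineError
from .molgraph import MolGraph, classify_atoms

_MODES = ("exactly_k_excl", "within_le_k", "pairs_le_k")
_KINDS = ("count", "charge_sum", "proximity")


@dataclass(frozen=True)
class DescriptorSpec:
    """Declarative definition of one descriptor column."""

    name: str
    kind: str  # "count" | "charge_sum" | "proximity"
    target_class: str
    source_class: str | None = None
    k: int | None = None
    mode: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "proximity":
            if self.mode not in _MODES:
                raise ConfigurationError(f"{self.name}: unknown mode {self.mode!r}")
            if self.source_class is None or self.k is None or self.k < 1:
                raise ConfigurationError(
                    f"{self.name}: proximity spec needs source_class and k >= 1"
                )


def _min_dist_to_sources(mol: MolGraph, sources: frozenset[int], b: int) -> float:
    candidates = [mol.dist[a, b] for a in sources if a != b]
    return min(candidates) if candidates else np.inf


def proximity_value(mol: MolGraph, spec: DescriptorSpec) -> int:
    """Evaluate a proximity descriptor on one molecule (0 for empty classes)."""
    sources = classify_atoms(mol, spec.source_class)
    targets = classify_atoms(mol, spec.target_class)
    if not sources or not targets:
        return 0
    k = spec.k
    if spec.mode == "pairs_le_k":
        return sum(
            1
            for a in sources
            for b in targets
            if a != b and 1 <= mol.dist[a, b] <= k
        )
    count = 0
    for b in targets:
        d = _min_dist_to_sources(mol, sources, b)
        if spec.mode == "exactly_k_excl":
            count += d == k
        else:  # within_le_k
            count += 1 <= d <= k
    return int(count)


def charge_sum_value(mol: MolGraph, cls: str) -> float:
    """Sum of partial charges over the atoms of a class (0.0 if empty)."""
    members = classify_atoms(mol, cls)
    return float(sum(mol.atoms[i].partial_charge for i in members))


def descriptor_value(mol: MolGraph, spec: DescriptorSpec) -> float:
    if spec.kind == "count":
        return float(len(classify_atoms(mol, spec.target_class)))
    if spec.kind == "charge_sum":
        return charge_sum_value(mol, spec.target_class)
    return float(proximity_value(mol, spec))


def named_descriptor_set() -> list[DescriptorSpec]:
    """The six model descriptors plus the ten comparator variants.

    Model descriptors: sum of partial charges on positively charged ring
    carbons; aromatic N within 4 bonds of sp2 C; and four "frequency at
    exactly k bonds" counts (amide N / Cl at 5; sp3 O / sp2 O at 6;
    sp3 O / sp2 N at 9; sp2 O / sp2 C at 8).
    """
    prox = DescriptorSpec
    return [
        # -- the six descriptors of the frozen model --
        prox("ringCplus_sumpc", "charge_sum", target_class="ringCplus"),
        prox("aroN_sp2C_4B", "proximity", "aroN", "sp2C", 4, "within_le_k"),
        prox("fClamdN5B", "proximity", "amideN", "Cl", 5, "exactly_k_excl"),
        prox("fsp2Osp3O6B", "proximity", "sp3O", "sp2O", 6, "exactly_k_excl"),
        prox("fsp2Nsp3O9B", "proximity", "sp3O", "sp2N", 9, "exactly_k_excl"),
        prox("fsp2Csp2O8B", "proximity", "sp2O", "sp2C", 8, "exactly_k_excl"),
        # -- comparator variants --
        prox("ringC", "count", target_class="ringC"),
        prox("nCplus", "count", target_class="Cplus"),
        prox("naroC", "count", target_class="aroC"),
        prox("naroCplus", "count", target_class="aroCplus"),
        prox("aroN", "count", target_class="aroN"),
        prox("nsp2C", "count", target_class="sp2C"),
        prox("aroN_sp2C_3B", "proximity", "aroN", "sp2C", 3, "within_le_k"),
        prox("aroN_sp2C_5B", "proximity", "aroN", "sp2C", 5, "within_le_k"),
        prox("sp3O_sp2O_6B", "proximity", "sp3O", "sp2O", 6, "within_le_k"),
        prox("sp3O_sp2N_9B", "proximity", "sp3O", "sp2N", 9, "within_le_k"),
    ]


MODEL_DESCRIPTOR_NAMES = tuple(s.name for s in named_descriptor_set()[:6])


def compute_matrix(
    mols: Sequence[MolGraph],
    specs: Sequence[DescriptorSpec],
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dense molecules x descriptors table (row order = input order)."""
    if ids is None:
        ids = [str(i) for i in range(len(mols))]
    if len(ids) != len(mols):
        raise PipelineError("ids and molecules differ in length")
    failed: list[str] = []
    rows = []
    for mol_id, mol in zip(ids, mols):
        try:
            rows.append([descriptor_value(mol, spec) for spec in specs])
        except Exception as exc:  # noqa: BLE001 - reported with molecule id
            failed.append(f"{mol_id}: {exc}")
            rows.append(None)
    if failed:
        raise PipelineError("descriptor computation failed for: " + "; ".join(failed))
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="id"),
                         columns=[s.name for s in specs], dtype=float)
    if frame.isna().any().any():
        raise PipelineError("descriptor matrix contains missing values")
    return frame


def matrix_provenance(specs: Sequence[DescriptorSpec]) -> dict:
    """Reproducibility metadata recorded next to every descriptor matrix."""
    import hashlib

    import rdkit

    payload = json.dumps([spec.__dict__ for spec in specs], sort_keys=True)
    return {
        "toolkit": f"rdkit-{rdkit.__version__}",
        "charge_scheme": "gasteiger",
        "spec_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "n_descriptors": len(specs),
    }


# --- user-defined descriptor registries --------------------------------------


def load_registry(path) -> list[DescriptorSpec]:
    """Load descriptor specs from a JSON registry file.

    Format: list of objects with keys ``name``, ``kind``, ``target``, and for
    proximity descriptors ``source``, ``k``, ``mode``.
    """
    with open(path) as handle:
        raw = json.load(handle)
    specs = []
    for entry in raw:
        specs.append(
            DescriptorSpec(
                name=entry["name"],
                kind=entry["kind"],
                target_class=entry["target"],
                source_class=entry.get("source"),
                k=entry.get("k"),
                mode=entry.get("mode"),
            )
        )
    return specs


def save_registry(specs: Sequence[DescriptorSpec], path) -> None:
    raw = [
        {
            "name": s.name,
            "kind": s.kind,
            "target": s.target_class,
            "source": s.source_class,
            "k": s.k,
            "mode": s.mode,
        }
        for s in specs
    ]
    with open(path, "w") as handle:
        json.dump(raw, handle, indent=2)
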