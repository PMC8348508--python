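"""Curate the library and compute the proximity-descriptor matrix.

Parses every SMILES into an annotated molecular graph, evaluates the sixteen
named descriptors (six model descriptors plus ten comparator variants), and
applies objective feature selection (constant / near-constant removal, then
|R| > 0.90 inter-correlation pruning guided by correlation with pKi).

Reads  results/library/activities.csv
Writes results/descriptors/{curated.csv,descriptors.csv,descriptors_ofs.csv}.
"""

import argparse
from pathlib import Path

import pandas as pd

from xaqsar.dataset import ofs_filter
from xaqsar.descriptors import compute_matrix, matrix_provenance, named_descriptor_set
from xaqsar.molgraph import curate, parse_molecule, read_activity_csv, write_curated_csv


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--input", default="results/library/activities.csv")
    parser.add_argument("--outdir", default="results/descriptors")
    args = parser.parse_args()

    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = curate(read_activity_csv(args.input))
    write_curated_csv(records, outdir / "curated.csv")
    print(f"curated {len(records)} molecules")

    specs = named_descriptor_set()
    mols = [parse_molecule(r.smiles, mol_id=r.id) for r in records]
    X = compute_matrix(mols, specs, ids=[r.id for r in records])
    X.to_csv(outdir / "descriptors.csv")
    print(f"descriptor matrix: {X.shape[0]} x {X.shape[1]} "
          f"({matrix_provenance(specs)['toolkit']})")

    y = pd.Series([r.pki for r in records], index=X.index, name="pki")
    X_ofs = ofs_filter(X, y, corr_cut=0.90, near_const_tol=0.05)
    X_ofs.to_csv(outdir / "descriptors_ofs.csv")
    dropped = sorted(set(X.columns) - set(X_ofs.columns))
    print(f"OFS kept {X_ofs.shape[1]}/{X.shape[1]} descriptors; dropped: {dropped}")


if __name__ == "__main__":
    main()
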