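"""End-to-end pipeline: curate -> descriptors -> OFS -> split -> GA-MLR per
size -> breaking point -> final fit -> full validation, with every artefact
written to a run directory and every output stamped with the config hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors as desc
from .dataset import ModelingTable, ofs_filter, split_dataset, write_split_csv
from .exceptions import PipelineError
from .molgraph import curate, parse_molecule, read_activity_csv, read_smi, write_curated_csv
from .selection import GAConfig, breaking_point, ga_mlr_search
from .validation import MLRModel, fit_mlr, predict, published_model, validate_model


@dataclass
class PipelineConfig:
    input_csv: str = ""
    outdir: str = "run"
    registry: str | None = None  # extra user descriptor specs (JSON)
    ofs_corr_cut: float = 0.90
    ofs_near_const_tol: float = 0.05
    split_fraction: float = 0.8
    max_m: int = 8
    delta: float = 0.02  # breaking-point gain threshold
    ga_population: int = 100
    ga_generations: int = 300
    ga_crossover_prob: float = 0.8
    ga_mutation_prob: float = 0.05
    ga_elitism: int = 2
    lmo_fraction: float = 0.3
    lmo_iterations: int = 1000
    yscr_iterations: int = 1000
    resid_cut: float = 2.5
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dump_json(obj, path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)


def model_to_dict(model: MLRModel) -> dict:
    return {
        "names": list(model.names),
        "intercept": model.intercept,
        "coef": list(map(float, model.coef)),
        "se_intercept": model.se_intercept,
        "se_coef": list(map(float, model.se_coef)),
        "n_train": model.n_train,
        "s": model.s,
        "provenance": model.provenance,
    }


def model_from_dict(raw: dict) -> MLRModel:
    return MLRModel(
        names=tuple(raw["names"]),
        intercept=float(raw["intercept"]),
        coef=np.asarray(raw["coef"], float),
        se_intercept=float(raw["se_intercept"]),
        se_coef=np.asarray(raw["se_coef"], float),
        n_train=int(raw["n_train"]),
        s=float(raw["s"]),
        provenance=raw.get("provenance", {}),
    )


def load_model(path) -> MLRModel:
    """Load a model JSON file; the literal string "published" returns the
    frozen published model."""
    if str(path) == "published":
        return published_model()
    with open(path) as handle:
        return model_from_dict(json.load(handle))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artefacts under ``config.outdir``.

    Re-running with an identical config reproduces identical numeric output
    (all randomness is derived from ``config.seed``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config), "config_hash": config.config_hash()}

    # stage 1: curation
    raw = read_activity_csv(config.input_csv)
    records = curate(raw)
    write_curated_csv(records, outdir / "curated.csv")
    log["n_curated"] = len(records)

    # stage 2: descriptors
    specs = desc.named_descriptor_set()
    if config.registry:
        specs = specs + desc.load_registry(config.registry)
    mols = [parse_molecule(r.smiles, mol_id=r.id) for r in records]
    ids = [r.id for r in records]
    X_full = desc.compute_matrix(mols, specs, ids=ids)
    X_full.to_csv(outdir / "descriptors.csv")
    _dump_json(desc.matrix_provenance(specs), outdir / "descriptor_provenance.json")

    # stage 3: OFS
    y = pd.Series([r.pki for r in records], index=X_full.index, name="pki")
    X = ofs_filter(
        X_full, y, corr_cut=config.ofs_corr_cut,
        near_const_tol=config.ofs_near_const_tol,
    )
    log["n_descriptors_raw"] = X_full.shape[1]
    log["n_descriptors_after_ofs"] = X.shape[1]

    # stage 4: split
    labels = split_dataset(len(records), config.split_fraction, seed=config.seed)
    write_split_csv(ids, labels, outdir / "split.csv")
    table = ModelingTable(records=records, X=X, y=y, labels=labels, seed=config.seed)

    # stage 5: GA-MLR per model size + breaking point
    ga_kwargs = dict(
        population=config.ga_population,
        generations=config.ga_generations,
        crossover_prob=config.ga_crossover_prob,
        mutation_prob=config.ga_mutation_prob,
        elitism=config.ga_elitism,
    )
    max_m = min(config.max_m, X.shape[1], int(len(table.y_train) / 5) - 1)
    if max_m < 3:
        raise PipelineError(f"cannot scan model sizes: max usable size {max_m} < 3")
    scores = []
    per_size = []
    for m in range(1, max_m + 1):
        cfg_m = GAConfig(seed=config.seed + m, **ga_kwargs)
        candidates = ga_mlr_search(table.X_train, table.y_train, m, cfg_m)
        best = candidates[0]
        scores.append((m, best.r2_tr, best.q2_loo))
        per_size.append(
            {
                "m": m,
                "best_subsets": [
                    {"names": list(c.names), "q2_loo": c.q2_loo, "r2_tr": c.r2_tr}
                    for c in candidates[:5]
                ],
            }
        )
    _dump_json(per_size, outdir / "selection_by_size.json")
    pd.DataFrame(scores, columns=["m", "R2_tr", "Q2_LOO"]).to_csv(
        outdir / "selection_curve.csv", index=False
    )
    m_star = breaking_point(scores, delta=config.delta)
    chosen = next(e for e in per_size if e["m"] == m_star)["best_subsets"][0]
    log["breaking_point"] = m_star
    log["delta"] = config.delta
    log["selected_descriptors"] = chosen["names"]

    # stage 6: final fit + validation
    names = chosen["names"]
    ids_arr = np.asarray(ids)
    model, report = validate_model(
        table.X_train[names],
        table.y_train,
        table.X_external[names],
        table.y_external,
        names=names,
        lmo_fraction=config.lmo_fraction,
        lmo_iterations=config.lmo_iterations,
        yscr_iterations=config.yscr_iterations,
        resid_cut=config.resid_cut,
        seed=config.seed,
        ids_train=ids_arr[table.train_mask],
        ids_ext=ids_arr[~table.train_mask],
    )
    _dump_json(model_to_dict(model), outdir / "model.json")
    report.to_json(outdir / "validation.json")
    report.ad.table.to_csv(outdir / "williams.csv", index=False)
    report.yscr.table.to_csv(outdir / "yscrambling.csv", index=False)

    import rdkit

    log["toolkit"] = f"rdkit-{rdkit.__version__}"
    _dump_json(log, outdir / "run_log.json")
    return outdir


def predict_activities(model: MLRModel, input_path) -> pd.DataFrame:
    """Predict pKi for the molecules of a CSV/.smi file with a fitted model."""
    path = str(input_path)
    raw = read_smi(path) if path.endswith(".smi") else read_activity_csv(path)
    ids = [str(r["id"]) for r in raw]
    mols = [parse_molecule(r["smiles"], mol_id=r["id"]) for r in raw]
    spec_by_name = {s.name: s for s in desc.named_descriptor_set()}
    specs = [spec_by_name[n] for n in model.names]
    X = desc.compute_matrix(mols, specs, ids=ids)
    return pd.DataFrame({"id": ids, "pki_pred": predict(model, X)})
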