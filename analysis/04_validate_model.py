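"""Fit the selected model and run the complete validation protocol.

Fits OLS on the breaking-point descriptor subset over the training rows, then
computes the full statistic block (training fit, leave-one-out and
leave-many-out cross-validation, Y-scrambling, external Q2-F1/F2/F3 and
concordance, through-origin r2m diagnostics) and the Williams applicability
domain, and compares the recovered coefficients with the frozen published
model that generated the activities.

Reads  results/descriptors/, results/selection/
Writes results/validation/{model.json,validation.json,williams.csv,
       yscrambling.csv,*.png}.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from xaqsar.pipeline import model_to_dict
from xaqsar.plots import plot_fit, plot_williams, plot_yscramble
from xaqsar.validation import predict, published_model, validate_model


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--descriptors", default="results/descriptors/descriptors_ofs.csv")
    parser.add_argument("--curated", default="results/descriptors/curated.csv")
    parser.add_argument("--selection", default="results/selection")
    parser.add_argument("--outdir", default="results/validation")
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    X = pd.read_csv(args.descriptors, index_col=0)
    curated = pd.read_csv(args.curated)
    y = pd.Series(curated["pki"].to_numpy(), index=X.index, name="pki")
    split = pd.read_csv(Path(args.selection) / "split.csv")
    train = (split["set"] == "train").to_numpy()
    sel = json.loads((Path(args.selection) / "selection_by_size.json").read_text())
    m_star = sel["breaking_point"]
    names = sel["sizes"][m_star - 1]["best_subsets"][0]["names"]
    print(f"fitting m = {m_star} descriptors: {names}")

    ids = curated["id"].astype(str).to_numpy()
    model, report = validate_model(
        X.loc[train, names], y[train], X.loc[~train, names], y[~train],
        names=names, seed=args.seed,
        ids_train=ids[train], ids_ext=ids[~train],
    )
    (outdir / "model.json").write_text(json.dumps(model_to_dict(model), indent=2))
    report.to_json(outdir / "validation.json")
    report.ad.table.to_csv(outdir / "williams.csv", index=False)
    report.yscr.table.to_csv(outdir / "yscrambling.csv", index=False)

    s = report.stats
    print(f"R2_tr={s['R2_tr']:.3f} Q2_LOO={s['Q2_LOO']:.3f} Q2_LMO={s['Q2_LMO']:.3f} "
          f"CCC_tr={s['CCC_tr']:.3f}")
    print(f"external: R2_ex={s.get('R2_ex', float('nan')):.3f} "
          f"Q2_F1={s['Q2_F1']:.3f} Q2_F2={s['Q2_F2']:.3f} Q2_F3={s['Q2_F3']:.3f} "
          f"CCC_ex={s['CCC_ex']:.3f}")
    print(f"Y-scrambling: mean R2_scr={s['R2_Yscr']:.3f} mean Q2_scr={s['Q2_Yscr']:.3f}")
    print(f"AD: h* = {s['h_star']:.3f}, "
          f"{int(report.ad.table['outlier'].sum())} outliers, "
          f"{int(report.ad.table['influential'].sum())} high-leverage molecules")

    # coefficient recovery against the generating model
    reference = published_model()
    ref = dict(zip(reference.names, reference.coef))
    rows = []
    for name, est, se in zip(model.names, model.coef, model.se_coef):
        true = ref.get(name, 0.0)
        rows.append({"descriptor": name, "estimate": est, "se": se,
                     "generating_value": true, "z": (est - true) / se})
    recovery = pd.DataFrame(rows)
    recovery.to_csv(outdir / "coefficient_recovery.csv", index=False)
    print("coefficient recovery (|z| = |estimate - generating| / SE):")
    print(recovery.round(3).to_string(index=False))

    # figures
    yhat = predict(model, X[names])
    plot_fit(y, yhat, outdir / "fit.png", sets=split["set"])
    plot_williams(report.ad.table, report.ad.h_star, report.ad.resid_cut,
                  outdir / "williams.png")
    plot_yscramble(report.yscr.table, report.yscr.kxy_unscrambled,
                   s["R2_tr"], s["Q2_LOO"], outdir / "yscramble.png")
    print(f"figures and tables -> {outdir}")


if __name__ == "__main__":
    main()
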