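"""Split the data and run GA-MLR subset selection across model sizes.

Randomly splits the curated set 80/20 into training and external molecules,
runs the genetic-algorithm search (fitness = leave-one-out Q2 of the OLS fit
on the training rows) for each model size m = 1..max, and locates the
breaking point: the size past which the Q2 gain falls below delta = 0.02.

Reads  results/descriptors/{curated.csv,descriptors_ofs.csv}
Writes results/selection/{split.csv,selection_curve.csv,selection_by_size.json,
       selection_curve.png}.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from xaqsar.dataset import split_dataset, write_split_csv
from xaqsar.plots import plot_selection_curve
from xaqsar.selection import GAConfig, breaking_point, ga_mlr_search


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--descriptors", default="results/descriptors/descriptors_ofs.csv")
    parser.add_argument("--curated", default="results/descriptors/curated.csv")
    parser.add_argument("--outdir", default="results/selection")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--max-m", type=int, default=8)
    parser.add_argument("--population", type=int, default=60)
    parser.add_argument("--generations", type=int, default=60)
    parser.add_argument("--delta", type=float, default=0.02)
    args = parser.parse_args()

    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    X = pd.read_csv(args.descriptors, index_col=0)
    curated = pd.read_csv(args.curated)
    y = pd.Series(curated["pki"].to_numpy(), index=X.index, name="pki")

    labels = split_dataset(len(X), 0.8, seed=args.seed)
    write_split_csv(curated["id"], labels, outdir / "split.csv")
    X_tr, y_tr = X[labels == "train"], y[labels == "train"]
    print(f"split: {sum(labels == 'train')} train / {sum(labels == 'external')} external")

    max_m = min(args.max_m, X.shape[1])
    scores, per_size = [], []
    for m in range(1, max_m + 1):
        cfg = GAConfig(population=args.population, generations=args.generations,
                       seed=args.seed + m)
        candidates = ga_mlr_search(X_tr, y_tr, m, cfg)
        best = candidates[0]
        scores.append((m, best.r2_tr, best.q2_loo))
        per_size.append({"m": m, "best_subsets": [
            {"names": list(c.names), "q2_loo": c.q2_loo, "r2_tr": c.r2_tr}
            for c in candidates[:5]]})
        print(f"m={m}: Q2_LOO={best.q2_loo:.3f} R2_tr={best.r2_tr:.3f} "
              f"{list(best.names)}")

    m_star = breaking_point(scores, delta=args.delta)
    print(f"breaking point at m = {m_star} (delta = {args.delta})")

    pd.DataFrame(scores, columns=["m", "R2_tr", "Q2_LOO"]).to_csv(
        outdir / "selection_curve.csv", index=False)
    (outdir / "selection_by_size.json").write_text(json.dumps(
        {"breaking_point": m_star, "delta": args.delta, "sizes": per_size}, indent=2))
    plot_selection_curve(scores, m_star, outdir / "selection_curve.png")


if __name__ == "__main__":
    main()
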