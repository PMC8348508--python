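"""Modeling-table assembly: objective feature selection and data splitting.

Objective feature selection (OFS) is the unsupervised pruning step applied
before any response-guided search: constant and near-constant descriptor
columns are dropped, then one member of every highly inter-correlated pair
(|Pearson R| above a cutoff, default 0.90) is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PipelineError
from .molgraph import ActivityRecord


@dataclass
class ModelingTable:
    """Aligned records, descriptor matrix, response and split labels."""

    records: list[ActivityRecord]
    X: pd.DataFrame
    y: pd.Series
    labels: np.ndarray  # "train" / "external" per row
    seed: int

    def __post_init__(self):
        n = len(self.records)
        if not (len(self.X) == len(self.y) == len(self.labels) == n):
            raise PipelineError("records, X, y and labels must align 1:1")

    @property
    def train_mask(self) -> np.ndarray:
        return self.labels == "train"

    @property
    def X_train(self) -> pd.DataFrame:
        return self.X.loc[self.train_mask]

    @property
    def y_train(self) -> pd.Series:
        return self.y.loc[self.train_mask]

    @property
    def X_external(self) -> pd.DataFrame:
        return self.X.loc[~self.train_mask]

    @property
    def y_external(self) -> pd.Series:
        return self.y.loc[~self.train_mask]


def ofs_filter(
    X: pd.DataFrame,
    y: pd.Series | None = None,
    corr_cut: float = 0.90,
    near_const_tol: float = 0.05,
) -> pd.DataFrame:
    """Remove constant, near-constant and highly inter-correlated columns.

    A column is near-constant when its most frequent value occupies more than
    ``1 - near_const_tol`` of the rows. Correlated pairs (|R| > ``corr_cut``)
    are resolved greedily in descending |R| order; the survivor is the column
    with the higher |correlation to y| when *y* is supplied, otherwise the
    earlier column.
    """
    if len(X) < 2:
        raise PipelineError("OFS needs at least two rows")
    n = len(X)
    kept = []
    for col in X.columns:
        values = X[col]
        if values.nunique(dropna=False) <= 1:
            continue
        if values.value_counts().iloc[0] > (1.0 - near_const_tol) * n:
            continue
        kept.append(col)
    if not kept:
        raise PipelineError("OFS removed every descriptor column")

    sub = X[kept]
    corr = sub.corr().abs().to_numpy()
    order = {c: i for i, c in enumerate(kept)}
    if y is not None:
        y_corr = sub.apply(lambda c: abs(np.corrcoef(c, y)[0, 1])).fillna(0.0)
    pairs = [
        (corr[i, j], i, j)
        for i in range(len(kept))
        for j in range(i + 1, len(kept))
        if corr[i, j] > corr_cut
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(kept)
    for _, i, j in pairs:
        ci, cj = kept[i], kept[j]
        if ci not in alive or cj not in alive:
            continue
        if y is not None and not np.isclose(y_corr[ci], y_corr[cj]):
            drop = ci if y_corr[ci] < y_corr[cj] else cj
        else:
            drop = cj  # keep the earlier column
        alive.discard(drop)
    survivors = [c for c in kept if c in alive]
    if not survivors:
        raise PipelineError("OFS removed every descriptor column")
    return X[survivors]


def split_dataset(n: int, train_fraction: float = 0.8, seed: int = 0) -> np.ndarray:
    """Random train/external labels; train size = round(train_fraction * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 records to split")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("degenerate split: one set would be empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.full(n, "external", dtype=object)
    labels[perm[:n_train]] = "train"
    return labels


def write_split_csv(ids, labels, path) -> None:
    pd.DataFrame({"id": ids, "set": labels}).to_csv(path, index=False)
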