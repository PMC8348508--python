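"""Genetic-algorithm descriptor-subset search scored by Q2_LOO, and the
breaking-point rule for choosing the model size.

Chromosomes are fixed-size descriptor subsets (index arrays). Selection is
tournament-based, crossover samples the child from the union of the two
parents' genes (which keeps the cardinality exact), and mutation swaps single
genes for random outside columns. Elitism makes the best fitness
non-decreasing across generations. Fitness is the leave-one-out Q2 of the
OLS fit, computed via the PRESS identity without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GAConfig:
    population: int = 100
    generations: int = 300
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05  # per gene
    elitism: int = 2
    tournament: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for prob in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ModelCandidate:
    names: tuple[str, ...]
    q2_loo: float
    r2_tr: float


def _subset_fitness(arr: np.ndarray, y: np.ndarray, idx: tuple[int, ...],
                    sstot: float, y_mean: float) -> tuple[float, float]:
    """(Q2_LOO, R2_tr) of the OLS fit on the given columns; -inf if singular."""
    D = np.column_stack([np.ones(len(y)), arr[:, idx]])
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    if diag.min() <= 1e-10 * diag.max():
        return -np.inf, -np.inf
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - D @ beta
    h = np.sum(q**2, axis=1)
    press = resid / np.clip(1.0 - h, 1e-12, None)
    q2 = 1.0 - float(press @ press) / sstot
    r2 = 1.0 - float(resid @ resid) / sstot
    return q2, r2


def ga_mlr_search(
    X: pd.DataFrame,
    y,
    m: int,
    cfg: GAConfig | None = None,
    return_history: bool = False,
):
    """Evolve fixed-size descriptor subsets; returns candidates ranked by Q2_LOO.

    Ties on fitness break lexicographically on the descriptor names. With
    ``return_history=True`` also returns the best fitness per generation.
    """
    cfg = cfg or GAConfig()
    cols = list(X.columns)
    arr = X.to_numpy(float)
    y = np.asarray(y, float)
    n, pool = arr.shape
    if m < 1 or m > pool:
        raise ValueError(f"model size m={m} outside descriptor pool of {pool}")
    if m >= n / 5:
        raise ValueError(f"m={m} too large for n={n} training rows (rule of 5)")
    y_mean = y.mean()
    sstot = float(np.sum((y - y_mean) ** 2))
    rng = np.random.default_rng(cfg.seed)

    cache: dict[tuple[int, ...], tuple[float, float]] = {}

    def fitness(idx: tuple[int, ...]) -> tuple[float, float]:
        if idx not in cache:
            cache[idx] = _subset_fitness(arr, y, idx, sstot, y_mean)
        return cache[idx]

    def sort_key(idx: tuple[int, ...]):
        q2, _ = fitness(idx)
        return (-q2, tuple(cols[i] for i in idx))

    population = [
        tuple(sorted(rng.choice(pool, size=m, replace=False)))
        for _ in range(cfg.population)
    ]
    history: list[float] = []
    for _ in range(cfg.generations):
        ranked = sorted(set(population), key=sort_key)
        history.append(fitness(ranked[0])[0])
        next_pop = list(ranked[: cfg.elitism])
        while len(next_pop) < cfg.population:
            parents = []
            for _ in range(2):
                contestants = [
                    population[i]
                    for i in rng.integers(0, len(population), cfg.tournament)
                ]
                parents.append(min(contestants, key=sort_key))
            if rng.random() < cfg.crossover_prob:
                union = sorted(set(parents[0]) | set(parents[1]))
                child = tuple(sorted(rng.choice(union, size=m, replace=False)))
            else:
                child = parents[0]
            # per-gene mutation: swap for a random column outside the subset
            child_set = set(child)
            for gene in child:
                if rng.random() < cfg.mutation_prob:
                    replacement = int(rng.integers(0, pool))
                    while replacement in child_set:
                        replacement = int(rng.integers(0, pool))
                    child_set.discard(gene)
                    child_set.add(replacement)
            next_pop.append(tuple(sorted(child_set)))
        population = next_pop

    ranked = sorted(set(population), key=sort_key)
    candidates = [
        ModelCandidate(
            names=tuple(cols[i] for i in idx),
            q2_loo=fitness(idx)[0],
            r2_tr=fitness(idx)[1],
        )
        for idx in ranked
    ]
    if return_history:
        history.append(candidates[0].q2_loo)
        return candidates, history
    return candidates


def breaking_point(scores, delta: float = 0.02) -> int:
    """Smallest model size m where the Q2_LOO gain to m+1 drops below delta.

    ``scores`` is a sequence of (m, R2_tr, Q2_LOO) for consecutive sizes
    m = 1..M (at least 3); returns M when no gain ever falls below delta.
    """
    scores = sorted(scores, key=lambda t: t[0])
    ms = [int(s[0]) for s in scores]
    if len(ms) < 3:
        raise ValueError("need scores for at least three consecutive sizes")
    if ms != list(range(ms[0], ms[0] + len(ms))):
        raise ValueError(f"model sizes must be consecutive integers, got {ms}")
    q2s = [float(s[2]) for s in scores]
    for i in range(len(ms) - 1):
        if q2s[i + 1] - q2s[i] < delta:
            return ms[i]
    return ms[-1]
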