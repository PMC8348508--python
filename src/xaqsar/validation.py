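"""OLS model fitting and the full QSAR validation-statistic suite.

Implements the training-set statistics (R2, adjusted R2, RMSE, MAE, F,
Lin's concordance correlation coefficient), leave-one-out and leave-many-out
cross-validation, Y-scrambling, the external-set predictivity family
(Q2-F1/F2/F3, CCC_ex, through-origin r2m diagnostics) and the Williams-plot
applicability domain, plus the frozen published six-descriptor model for
factor Xa inhibition.

Conventions: CCC uses population (1/n) moments. Q2_LOO is computed from the
PRESS identity e_i / (1 - h_i) without refitting; rows with leverage
numerically 1 fall back to an explicit refit. Q2_LMO pools squared errors
over rounds: 1 - sum(out-of-group squared errors) / sum((y - y_bar_full)^2
over the same rows), which reduces exactly to Q2_LOO when the groups are the
n singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    SchemaError,
    SingularDesignError,
    UndefinedStatisticError,
)

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class MLRModel:
    """A fitted (or transcribed) multilinear regression model."""

    names: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    se_intercept: float
    se_coef: np.ndarray
    n_train: int
    s: float  # residual standard deviation
    provenance: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.names)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _as_array(X, names: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = tuple(X.columns)
        else:
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise SchemaError(f"missing descriptor columns: {missing}")
        return X[list(names)].to_numpy(float), tuple(names)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    return X, tuple(names)


def fit_mlr(X, y, names: Sequence[str] | None = None) -> MLRModel:
    """Ordinary least squares with intercept; standard errors from s^2 (X'X)^-1."""
    Xa, names = _as_array(X, names)
    y = np.asarray(y, float)
    n, p = Xa.shape
    if n <= p + 1:
        raise SingularDesignError(f"need n > p + 1 (n={n}, p={p})")
    D = _design(Xa)
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    bad = diag <= _RANK_TOL * diag.max()
    if bad.any():
        offenders = [(["intercept"] + list(names))[i] for i in np.where(bad)[0]]
        raise SingularDesignError(f"rank-deficient design; collinear: {offenders}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - D @ beta
    dof = n - p - 1
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(r.T @ r)
    se = np.sqrt(np.diag(cov))
    return MLRModel(
        names=names,
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        se_intercept=float(se[0]),
        se_coef=se[1:].copy(),
        n_train=n,
        s=float(np.sqrt(s2)),
        provenance={"fit": "ols"},
    )


def predict(model: MLRModel, X) -> np.ndarray:
    """Apply a model: intercept + X . coef, columns matched by name."""
    Xa, _ = _as_array(X, model.names)
    if Xa.shape[1] != model.p:
        raise SchemaError(
            f"expected {model.p} descriptor columns, got {Xa.shape[1]}"
        )
    return model.intercept + Xa @ model.coef


def published_model() -> MLRModel:
    """The frozen six-descriptor factor Xa model, coefficients as printed.

    pKi = 6.176 + 1.513*ringCplus_sumpc + 0.519*aroN_sp2C_4B
          + 1.197*fClamdN5B - 1.018*fsp2Osp3O6B - 1.091*fsp2Nsp3O9B
          - 0.9*fsp2Csp2O8B
    """
    return MLRModel(
        names=(
            "ringCplus_sumpc",
            "aroN_sp2C_4B",
            "fClamdN5B",
            "fsp2Osp3O6B",
            "fsp2Nsp3O9B",
            "fsp2Csp2O8B",
        ),
        intercept=6.176,
        coef=np.array([1.513, 0.519, 1.197, -1.018, -1.091, -0.9]),
        se_intercept=0.073,
        se_coef=np.array([0.104, 0.04, 0.077, 0.099, 0.111, 0.158]),
        n_train=897,
        s=0.478,
        provenance={"source": "published", "target": "factor Xa Ki (pKi, M)"},
    )


# --- scalar statistics --------------------------------------------------------


def r2(y, yhat) -> float:
    """Coefficient of determination, 1 - SSres/SStot."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise UndefinedStatisticError("R2 undefined: zero variance in y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def rmse(y, yhat) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return float(np.mean(np.abs(y - yhat)))


def ccc(y, yhat) -> float:
    """Lin's concordance correlation coefficient with population moments."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    var_y = float(np.var(y))
    var_h = float(np.var(yhat))
    if var_y == 0.0:
        raise UndefinedStatisticError("CCC undefined: zero variance in y")
    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    return 2.0 * cov / (var_y + var_h + (y.mean() - yhat.mean()) ** 2)


def pearson_r2(y, yhat) -> float:
    """Squared Pearson correlation (the r^2 of the external r2m block)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if np.var(y) == 0.0 or np.var(yhat) == 0.0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


# --- cross-validation ---------------------------------------------------------


def _hat_diag_and_resid(Xa: np.ndarray, y: np.ndarray):
    D = _design(Xa)
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    if (diag <= _RANK_TOL * diag.max()).any():
        raise SingularDesignError("rank-deficient design in cross-validation")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - D @ beta
    h = np.sum(q**2, axis=1)
    return h, resid


@dataclass(frozen=True)
class LOOResult:
    q2: float
    rmse_cv: float
    ccc_cv: float
    predictions: np.ndarray


def q2_loo(X, y, names: Sequence[str] | None = None) -> LOOResult:
    """Leave-one-out Q2 via the PRESS identity e_i / (1 - h_i)."""
    Xa, names = _as_array(X, names)
    y = np.asarray(y, float)
    h, resid = _hat_diag_and_resid(Xa, y)
    press_resid = np.empty_like(resid)
    ok = h < 1.0 - 1e-8
    press_resid[ok] = resid[ok] / (1.0 - h[ok])
    for i in np.where(~ok)[0]:  # leverage one: explicit refit without row i
        keep = np.arange(len(y)) != i
        model = fit_mlr(Xa[keep], y[keep], names)
        press_resid[i] = y[i] - predict(model, Xa[i : i + 1])[0]
    loo_pred = y - press_resid
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise UndefinedStatisticError("Q2 undefined: zero variance in y")
    q2 = 1.0 - float(press_resid @ press_resid) / sstot
    return LOOResult(q2, rmse(y, loo_pred), ccc(y, loo_pred), loo_pred)


def q2_lmo(
    X,
    y,
    names: Sequence[str] | None = None,
    leave_fraction: float = 0.3,
    iterations: int = 1000,
    seed: int = 0,
    groups: Sequence[Sequence[int]] | None = None,
) -> float:
    """Leave-many-out Q2, pooled over rounds against the full-sample mean.

    ``groups`` overrides the random draws with explicit left-out index sets
    (useful to reproduce leave-one-out exactly).
    """
    Xa, names = _as_array(X, names)
    y = np.asarray(y, float)
    n, p = Xa.shape
    if groups is None:
        if not 0.0 < leave_fraction <= 0.5:
            raise ValueError("leave_fraction must lie in (0, 0.5]")
        n_out = max(1, int(round(leave_fraction * n)))
        rng = np.random.default_rng(seed)
        groups = [rng.choice(n, size=n_out, replace=False) for _ in range(iterations)]
    y_mean = y.mean()
    num = 0.0
    den = 0.0
    for out in groups:
        out = np.asarray(out, int)
        keep = np.setdiff1d(np.arange(n), out)
        if len(keep) < p + 2:
            raise ValueError("leave-many-out group leaves too few training rows")
        model = fit_mlr(Xa[keep], y[keep], names)
        pred = predict(model, Xa[out])
        num += float(np.sum((y[out] - pred) ** 2))
        den += float(np.sum((y[out] - y_mean) ** 2))
    if den == 0.0:
        raise UndefinedStatisticError("Q2_LMO undefined: zero variance in left-out y")
    return 1.0 - num / den


# --- external validation ------------------------------------------------------


def external_stats(model: MLRModel, X_ext, y_ext, y_train) -> dict:
    """External predictivity block: Q2-F1/F2/F3, CCC, r2m/through-origin family."""
    y = np.asarray(y_ext, float)
    y_tr = np.asarray(y_train, float)
    yhat = predict(model, X_ext)
    n_ext = len(y)
    press = float(np.sum((y - yhat) ** 2))
    ss_tr = float(np.sum((y_tr - y_tr.mean()) ** 2))
    out: dict = {
        "RMSE_ex": rmse(y, yhat),
        "MAE_ex": mae(y, yhat),
        "Q2_F1": 1.0 - press / float(np.sum((y - y_tr.mean()) ** 2)),
        "Q2_F3": 1.0 - (press / n_ext) / (ss_tr / len(y_tr)),
        "CCC_ex": ccc(y, yhat),
    }
    ss_ext = float(np.sum((y - y.mean()) ** 2))
    if ss_ext == 0.0:
        out["Q2_F2"] = float("nan")
        out["zero_external_variance"] = True
        return out
    out["Q2_F2"] = 1.0 - press / ss_ext

    r2_ex = pearson_r2(y, yhat)
    # through-origin regressions: yhat ~ k*y and y ~ k'*yhat
    k = float(np.sum(y * yhat) / np.sum(y**2))
    k_prime = float(np.sum(y * yhat) / np.sum(yhat**2))
    ro2 = 1.0 - float(np.sum((yhat - k * y) ** 2)) / float(
        np.sum((yhat - yhat.mean()) ** 2)
    )
    ro2_prime = 1.0 - float(np.sum((y - k_prime * yhat) ** 2)) / ss_ext
    out.update(
        {
            "R2_ex": r2_ex,
            "k": k,
            "k_prime": k_prime,
            "Ro2": ro2,
            "Ro2_prime": ro2_prime,
            "r2m": r2_ex * (1.0 - np.sqrt(abs(r2_ex - ro2))),
            "r2m_prime": r2_ex * (1.0 - np.sqrt(abs(r2_ex - ro2_prime))),
            "delta_r2_Ro2": 1.0 - ro2 / r2_ex,
            "delta_r2_Ro2_prime": 1.0 - ro2_prime / r2_ex,
        }
    )
    return out


# --- Y-scrambling -------------------------------------------------------------


def k_correlation(M: np.ndarray) -> float:
    """Todeschini's K multivariate correlation index of a column block."""
    M = np.asarray(M, float)
    corr = np.corrcoef(M, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    p = corr.shape[0]
    total = lam.sum()
    if total == 0.0 or p < 2:
        return 0.0
    return float(np.sum(np.abs(lam / total - 1.0 / p)) / (2.0 * (p - 1) / p))


@dataclass
class YScrambleResult:
    r2_mean: float
    q2_mean: float
    r2_max: float
    q2_max: float
    kxy_unscrambled: float
    table: pd.DataFrame  # per-iteration r2, q2, kxy


def y_scramble(
    X, y, names: Sequence[str] | None = None, n_iter: int = 1000, seed: int = 0
) -> YScrambleResult:
    """Refit after permuting the response; identity permutations are redrawn."""
    if n_iter < 100:
        raise ValueError("y_scramble needs n_iter >= 100")
    Xa, names = _as_array(X, names)
    y = np.asarray(y, float)
    n = len(y)
    rng = np.random.default_rng(seed)
    rows = []
    block = np.column_stack([Xa, y])
    kxy0 = k_correlation(block)
    for _ in range(n_iter):
        perm = rng.permutation(n)
        while np.array_equal(perm, np.arange(n)):
            perm = rng.permutation(n)
        y_perm = y[perm]
        h, resid = _hat_diag_and_resid(Xa, y_perm)
        sstot = float(np.sum((y_perm - y_perm.mean()) ** 2))
        r2_i = 1.0 - float(resid @ resid) / sstot
        press = resid / np.clip(1.0 - h, 1e-12, None)
        q2_i = 1.0 - float(press @ press) / sstot
        kxy_i = k_correlation(np.column_stack([Xa, y_perm]))
        rows.append((r2_i, q2_i, kxy_i))
    table = pd.DataFrame(rows, columns=["r2_scr", "q2_scr", "kxy"])
    return YScrambleResult(
        r2_mean=float(table["r2_scr"].mean()),
        q2_mean=float(table["q2_scr"].mean()),
        r2_max=float(table["r2_scr"].max()),
        q2_max=float(table["q2_scr"].max()),
        kxy_unscrambled=kxy0,
        table=table,
    )


# --- applicability domain -----------------------------------------------------


@dataclass
class ADResult:
    table: pd.DataFrame  # id, set, leverage, std_residual, outlier, influential
    h_star: float
    resid_cut: float


def williams_ad(
    model: MLRModel,
    X_train,
    y_train,
    X_ext=None,
    y_ext=None,
    resid_cut: float = 2.5,
    ids_train=None,
    ids_ext=None,
) -> ADResult:
    """Leverages and standardized residuals for the Williams plot.

    Leverage h_i = x_i' (X'X)^-1 x_i with X'X from the training design;
    threshold h* = 3(p+1)/n_train. Residuals are standardized by the model's
    residual SD; |std residual| > ``resid_cut`` flags a response outlier,
    h > h* flags a structurally influential molecule.
    """
    Xt, _ = _as_array(X_train, model.names)
    y_tr = np.asarray(y_train, float)
    D = _design(Xt)
    xtx = D.T @ D
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise SingularDesignError("singular X'X in applicability-domain computation")
    xtx_inv = np.linalg.inv(xtx)
    h_star = 3.0 * (model.p + 1) / len(y_tr)

    def block(Xa, y, labels, ids):
        Da = _design(Xa)
        lev = np.einsum("ij,jk,ik->i", Da, xtx_inv, Da)
        std_resid = (y - (model.intercept + Xa @ model.coef)) / model.s
        if ids is None:
            ids = [f"{labels}_{i}" for i in range(len(y))]
        return pd.DataFrame(
            {
                "id": list(ids),
                "set": labels,
                "leverage": lev,
                "std_residual": std_resid,
            }
        )

    frames = [block(Xt, y_tr, "train", ids_train)]
    if X_ext is not None and y_ext is not None and len(np.asarray(y_ext)) > 0:
        Xe, _ = _as_array(X_ext, model.names)
        frames.append(block(Xe, np.asarray(y_ext, float), "external", ids_ext))
    table = pd.concat(frames, ignore_index=True)
    table["outlier"] = table["std_residual"].abs() > resid_cut
    table["influential"] = table["leverage"] > h_star
    return ADResult(table=table, h_star=h_star, resid_cut=resid_cut)


# --- full report --------------------------------------------------------------


@dataclass
class ValidationReport:
    stats: dict
    ad: ADResult
    yscr: YScrambleResult

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as handle:
            json.dump(self.stats, handle, indent=2, sort_keys=True)


def validate_model(
    X_train,
    y_train,
    X_ext,
    y_ext,
    names: Sequence[str] | None = None,
    lmo_fraction: float = 0.3,
    lmo_iterations: int = 1000,
    yscr_iterations: int = 1000,
    resid_cut: float = 2.5,
    seed: int = 0,
    ids_train=None,
    ids_ext=None,
) -> tuple[MLRModel, ValidationReport]:
    """Fit on the training rows and compute the complete statistic block."""
    model = fit_mlr(X_train, y_train, names)
    Xt, names = _as_array(X_train, model.names)
    y_tr = np.asarray(y_train, float)
    yhat_tr = predict(model, Xt)
    n, p = Xt.shape
    r2_tr = r2(y_tr, yhat_tr)
    ssres = float(np.sum((y_tr - yhat_tr) ** 2))
    ssreg = float(np.sum((yhat_tr - y_tr.mean()) ** 2))
    loo = q2_loo(Xt, y_tr, names)
    lmo = q2_lmo(
        Xt, y_tr, names, leave_fraction=lmo_fraction, iterations=lmo_iterations,
        seed=seed,
    )
    yscr = y_scramble(Xt, y_tr, names, n_iter=yscr_iterations, seed=seed)
    stats = {
        "n_train": n,
        "p": p,
        "R2_tr": r2_tr,
        "R2_adj": 1.0 - (1.0 - r2_tr) * (n - 1) / (n - p - 1),
        "RMSE_tr": rmse(y_tr, yhat_tr),
        "MAE_tr": mae(y_tr, yhat_tr),
        "s": model.s,
        "F": (ssreg / p) / (ssres / (n - p - 1)),
        "CCC_tr": ccc(y_tr, yhat_tr),
        "Q2_LOO": loo.q2,
        "RMSE_cv": loo.rmse_cv,
        "CCC_cv": loo.ccc_cv,
        "Q2_LMO": lmo,
        "R2_Yscr": yscr.r2_mean,
        "Q2_Yscr": yscr.q2_mean,
        "Kxy": yscr.kxy_unscrambled,
    }
    ad = williams_ad(
        model, Xt, y_tr, X_ext, y_ext, resid_cut=resid_cut,
        ids_train=ids_train, ids_ext=ids_ext,
    )
    stats["h_star"] = ad.h_star
    if X_ext is not None and y_ext is not None and len(np.asarray(y_ext)) > 0:
        stats.update(external_stats(model, X_ext, y_ext, y_tr))
    report = ValidationReport(stats=stats, ad=ad, yscr=yscr)
    return model, report
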