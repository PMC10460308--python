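"""Multiple imputation by chained equations (MICE).

Per-variable conditional models are cycled to produce ``m`` completed
datasets: predictive mean matching (Bayesian linear regression, k nearest
donors) for continuous variables, logistic draws for binary variables and
polytomous (multinomial) draws for categoricals.  Every draw is taken with
parameter uncertainty (posterior/asymptotic perturbation), as required for
Rubin-pooled inference downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["mice_impute", "infer_variable_types"]


def infer_variable_types(table: pd.DataFrame) -> dict[str, str]:
    """Map each column to 'continuous', 'binary' or 'categorical'."""
    types = {}
    for c in table.columns:
        col = table[c]
        if pd.api.types.is_numeric_dtype(col):
            types[c] = "continuous"
        else:
            types[c] = "binary" if col.dropna().nunique() <= 2 else "categorical"
    return types


def _encode_predictors(data: pd.DataFrame, exclude: str, types: dict[str, str]) -> np.ndarray:
    """Design matrix (with intercept) from all variables except ``exclude``."""
    blocks = [np.ones((len(data), 1))]
    for c in data.columns:
        if c == exclude:
            continue
        if types[c] == "continuous":
            x = data[c].to_numpy(dtype=float)
            sd = x.std()
            blocks.append(((x - x.mean()) / (sd if sd > 0 else 1.0))[:, None])
        else:
            levels = sorted(data[c].dropna().unique())
            for lev in levels[1:]:
                blocks.append((data[c] == lev).to_numpy(dtype=float)[:, None])
    return np.concatenate(blocks, axis=1)


def _pmm_draw(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive-mean-matching draw for continuous targets."""
    n, q = X_obs.shape
    XtX = X_obs.T @ X_obs + 1e-8 * np.eye(q)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - q, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    beta_star = rng.multivariate_normal(beta_hat, sigma2 * XtX_inv, method="cholesky")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    out = np.empty(len(X_mis))
    kk = min(k, n)
    for i, pm in enumerate(pred_mis):
        idx = np.argpartition(np.abs(pred_obs - pm), kk - 1)[:kk]
        out[i] = y_obs[idx[rng.integers(kk)]]
    return out


def _categorical_draw(
    y_obs: pd.Series,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Polytomous (or logistic) imputation draw with parameter perturbation."""
    levels = sorted(y_obs.unique())
    codes = pd.Categorical(y_obs, categories=levels).codes
    try:
        if len(levels) == 2:
            fit = sm.Logit(codes, X_obs).fit(disp=0, maxiter=200)
        else:
            fit = sm.MNLogit(codes, X_obs).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params).ravel(order="F")
        cov = np.asarray(fit.cov_params())
        cov = (cov + cov.T) / 2 + 1e-10 * np.eye(len(params))
        draw = rng.multivariate_normal(params, cov, method="eigh")
        if len(levels) == 2:
            eta = X_mis @ draw
            p1 = 1.0 / (1.0 + np.exp(-eta))
            probs = np.column_stack([1 - p1, p1])
        else:
            B = draw.reshape(X_obs.shape[1], len(levels) - 1, order="F")
            eta = np.clip(X_mis @ B, -30, 30)
            expo = np.column_stack([np.ones(len(X_mis)), np.exp(eta)])
            probs = expo / expo.sum(axis=1, keepdims=True)
    except Exception as exc:  # separation / singular fits: marginal fallback
        logger.warning("categorical imputation model failed (%s); marginal draw", exc)
        marg = pd.Series(codes).value_counts(normalize=True).sort_index()
        probs = np.tile(marg.to_numpy(), (len(X_mis), 1))
    u = rng.random(len(X_mis))
    drawn = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.asarray(levels, dtype=object)[np.clip(drawn, 0, len(levels) - 1)]


def mice_impute(
    table: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_iter: int = 10,
    pmm_k: int = 5,
    variable_types: dict[str, str] | None = None,
) -> list[pd.DataFrame]:
    """Produce ``m`` completed copies of ``table`` by chained equations.

    Each imputation runs its own chain (initialised from random observed
    draws) for ``n_iter`` cycles.  A table with no missing cells returns
    ``m`` identical copies.  Deterministic given ``seed``.
    """
    if m < 2:
        raise ValueError("at least two imputations are required")
    types = variable_types or infer_variable_types(table)
    missing_cols = [c for c in table.columns if table[c].isna().any()]
    for c in missing_cols:
        if table[c].dropna().nunique() < 2:
            raise ValueError(f"variable {c!r} is constant but has missing values")
        if table[c].notna().sum() == 0:
            raise ValueError(f"variable {c!r} has no observed values")
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(m)]
    completed = []
    for chain in range(m):
        rng = rngs[chain]
        data = table.copy()
        # initial fill: random observed donors
        for c in missing_cols:
            obs = table[c].dropna().to_numpy()
            mis = data[c].isna()
            data.loc[mis, c] = rng.choice(obs, size=int(mis.sum()))
        for _ in range(n_iter if missing_cols else 0):
            for c in missing_cols:
                mis = table[c].isna().to_numpy()
                X = _encode_predictors(data, c, types)
                if types[c] == "continuous":
                    y_obs = table.loc[~mis, c].to_numpy(dtype=float)
                    data.loc[mis, c] = _pmm_draw(y_obs, X[~mis], X[mis], pmm_k, rng)
                else:
                    data.loc[mis, c] = _categorical_draw(
                        table.loc[~mis, c], X[~mis], X[mis], rng
                    )
        for c in table.columns:
            if types[c] == "continuous":
                data[c] = data[c].astype(float)
        completed.append(data)
    return completed
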