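"""Descriptive group comparisons and MI-pooled multinomial regression.

Categorical variables are compared across groups by the chi-square test of
independence (no continuity correction), ordinal/continuous variables by
the Kruskal-Wallis test with tie correction.  Group membership is modelled
by multinomial logistic regression (reference = no-substance-use group);
with multiply-imputed data, per-imputation fits are combined with Rubin's
rules and Barnard-Rubin degrees of freedom, reported as relative risk
ratios (RRR = exponentiated coefficients).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .impute import mice_impute
from .instrument import GROUP_LEVELS
from .synthetic import DIAG_LEVELS, EDU_LEVELS, SCALE_SPECS

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "PooledEffect",
    "compare_groups",
    "fit_multinomial",
    "pool_rubin",
    "pooled_regression",
    "build_analysis_table",
]


@dataclass
class GroupComparison:
    variable: str
    test: str  # chi_square | kruskal_wallis
    statistic: float
    p: float
    summary: pd.DataFrame  # per-group counts or median/IQR
    warning: str | None = None


@dataclass
class PooledEffect:
    term: str
    outcome: str  # contrasted group (vs reference)
    estimate: float  # pooled log-RRR
    rrr: float
    ci_low: float
    ci_high: float
    p: float
    m: int
    within_var: float
    between_var: float
    df: float


def compare_groups(
    table: pd.DataFrame, variable: str, grouping: str
) -> GroupComparison:
    """Compare one variable across groups; test chosen by variable type."""
    data = table[[variable, grouping]].dropna()
    groups = [g for g, sub in data.groupby(grouping, observed=True) if len(sub)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    warning = None
    if pd.api.types.is_numeric_dtype(data[variable]):
        samples = [
            sub[variable].to_numpy(dtype=float)
            for _, sub in data.groupby(grouping, observed=True)
            if len(sub)
        ]
        if all(np.all(s == samples[0][0]) for s in samples):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*samples)
        summary = (
            data.groupby(grouping, observed=True)[variable]
            .agg(
                median="median",
                q1=lambda s: s.quantile(0.25),
                q3=lambda s: s.quantile(0.75),
                n="count",
            )
        )
        return GroupComparison(variable, "kruskal_wallis", float(stat), float(p), summary)
    counts = pd.crosstab(data[variable], data[grouping])
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2:
        stat, p = 0.0, 1.0
        expected = counts.to_numpy(dtype=float)
    else:
        stat, p, _, expected = stats.chi2_contingency(counts, correction=False)
    if (np.asarray(expected) < 1).any():
        warning = "expected cell count < 1; consider Fisher's exact test"
        logger.warning("%s: %s", variable, warning)
    return GroupComparison(
        variable, "chi_square", float(stat), float(p), counts, warning
    )


def _design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode a covariate frame (reference = first listed level)."""
    blocks = {"const": np.ones(len(design))}
    reference_orders = {
        "sex_at_birth": ("female", "male"),
        "lgbtiqa": ("no", "yes"),
        "region": ("metro", "regional"),
        "education_employment": EDU_LEVELS,
        "primary_diagnosis": DIAG_LEVELS,
    }
    for c in design.columns:
        col = design[c]
        if pd.api.types.is_numeric_dtype(col):
            blocks[c] = col.to_numpy(dtype=float)
        else:
            levels = reference_orders.get(c) or tuple(sorted(col.dropna().unique()))
            for lev in levels[1:]:
                blocks[f"{c}[{lev}]"] = (col == lev).to_numpy(dtype=float)
    return pd.DataFrame(blocks, index=design.index)


def fit_multinomial(
    design: pd.DataFrame,
    outcome: pd.Series,
    reference: str = "none",
    zscore: tuple[str, ...] = (),
    separation_threshold: float = 15.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Maximum-likelihood multinomial logistic regression.

    Returns the coefficient vector and its covariance, with parameter names
    ``"<outcome level>|<term>"``.  Columns named in ``zscore`` are
    standardised (complete-data mean/sd) before fitting.  Coefficients
    larger than ``separation_threshold`` on the standardised scale raise an
    error naming the term (a symptom of separation).
    """
    keep = outcome.notna() & design.notna().all(axis=1)
    y = outcome[keep]
    X = design[keep].copy()
    for c in zscore:
        x = X[c].astype(float)
        sd = x.std(ddof=1)
        X[c] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    levels = [reference] + [
        lev for lev in (
            y.cat.categories if hasattr(y, "cat") else sorted(y.unique())
        )
        if lev != reference and (y == lev).any()
    ]
    codes = pd.Categorical(y, categories=levels).codes
    Xmat = _design_matrix(X)
    rank = np.linalg.matrix_rank(Xmat.to_numpy())
    if rank < Xmat.shape[1]:
        raise ValueError("design matrix is rank deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(codes, Xmat.to_numpy()).fit(
                method="newton", maxiter=200, disp=0, tol=1e-10
            )
    except np.linalg.LinAlgError as exc:
        # Newton's Hessian goes singular when a term separates the outcome
        raise ValueError(f"separation suspected (singular Hessian): {exc}") from exc
    names = [
        f"{lev}|{term}" for lev in levels[1:] for term in Xmat.columns
    ]
    params = pd.Series(np.asarray(fit.params).ravel(order="F"), index=names)
    cov = pd.DataFrame(np.asarray(fit.cov_params()), index=names, columns=names)
    bad = params[(params.abs() > separation_threshold) & ~params.index.str.endswith("|const")]
    if len(bad):
        raise ValueError(f"separation suspected for term(s) {list(bad.index)}")
    return params, cov


def pool_rubin(
    fits: list[tuple[pd.Series, pd.DataFrame]], n_obs: int | None = None
) -> list[PooledEffect]:
    """Combine repeated-imputation fits with Rubin's rules.

    Total variance ``T = Ubar + (1 + 1/m) B``; intervals and p-values use
    Barnard-Rubin adjusted degrees of freedom (infinite when ``n_obs`` is
    not supplied and B = 0).
    """
    if len(fits) < 2:
        raise ValueError("pooling requires at least two fits")
    index = fits[0][0].index
    for params, cov in fits[1:]:
        if not params.index.equals(index):
            raise ValueError("imputation fits have mismatched terms")
    m = len(fits)
    est = np.vstack([f[0].to_numpy() for f in fits])
    wvar = np.vstack([np.diag(f[1].to_numpy()) for f in fits])
    qbar = est.mean(axis=0)
    ubar = wvar.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    T = ubar + (1 + 1 / m) * b
    out = []
    for i, name in enumerate(index):
        lam = (1 + 1 / m) * b[i] / T[i] if T[i] > 0 else 0.0
        if lam <= 0:
            df = np.inf if n_obs is None else max(n_obs - len(index), 1)
        else:
            df_old = (m - 1) / lam**2
            if n_obs is None:
                df = df_old
            else:
                nu_com = max(n_obs - len(index), 1)
                df_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
                df = df_old * df_obs / (df_old + df_obs)
        se = np.sqrt(T[i])
        tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
        if se > 0:
            pval = (
                2 * stats.t.sf(abs(qbar[i]) / se, df)
                if np.isfinite(df)
                else 2 * stats.norm.sf(abs(qbar[i]) / se)
            )
        else:
            pval = float(qbar[i] == 0)
        outcome, _, term = name.partition("|") if "|" in name else ("", "", name)
        out.append(
            PooledEffect(
                term=term,
                outcome=outcome,
                estimate=float(qbar[i]),
                rrr=float(np.exp(qbar[i])),
                ci_low=float(np.exp(qbar[i] - tcrit * se)),
                ci_high=float(np.exp(qbar[i] + tcrit * se)),
                p=float(pval),
                m=m,
                within_var=float(ubar[i]),
                between_var=float(b[i]),
                df=float(df),
            )
        )
    return out


SCALE_COLUMNS = tuple(SCALE_SPECS)
REGRESSION_COVARIATES = (
    "age",
    "sex_at_birth",
    "lgbtiqa",
    "region",
    "education_employment",
    "primary_diagnosis",
) + SCALE_COLUMNS


def build_analysis_table(cohort: pd.DataFrame, group: pd.Series) -> pd.DataFrame:
    """Regression table: group outcome + covariates, dropping group-missing rows.

    Group membership is the analysis stratum and is never imputed; rows
    where it cannot be resolved are excluded before imputation.
    """
    table = cohort[[c for c in REGRESSION_COVARIATES if c in cohort.columns]].copy()
    table.insert(0, "group", pd.Series(group, index=cohort.index))
    table = table[table["group"].notna()].reset_index(drop=True)
    return table


def pooled_regression(
    analysis_table: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_iter: int = 10,
    reference: str = "none",
) -> pd.DataFrame:
    """MICE + multinomial fit + Rubin pooling; one row per term x outcome.

    With no missing data the pooled estimates equal the single complete-data
    fit exactly (all chains return identical tables).
    """
    if analysis_table.drop(columns=["group"]).isna().any().any():
        # group is complete by construction, so it acts as a predictor in
        # the imputation models (standard MICE practice) but is never imputed
        completed = [
            c.drop(columns=["group"])
            for c in mice_impute(analysis_table, m=m, seed=seed, n_iter=n_iter)
        ]
    else:
        completed = [analysis_table.drop(columns=["group"]).copy() for _ in range(m)]
    outcome = pd.Categorical(
        analysis_table["group"],
        categories=[g for g in GROUP_LEVELS if (analysis_table["group"] == g).any()],
    )
    outcome = pd.Series(outcome, index=analysis_table.index)
    zscore = tuple(c for c in SCALE_COLUMNS if c in analysis_table.columns)
    fits = [
        fit_multinomial(comp, outcome, reference=reference, zscore=zscore)
        for comp in completed
    ]
    pooled = pool_rubin(fits, n_obs=len(analysis_table))
    rows = [
        {
            "outcome": e.outcome,
            "term": e.term,
            "rrr": e.rrr,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "p": e.p,
            "estimate": e.estimate,
            "within_var": e.within_var,
            "between_var": e.between_var,
            "df": e.df,
            "m": e.m,
        }
        for e in pooled
    ]
    return pd.DataFrame(rows)
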