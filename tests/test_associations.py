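"""Group comparisons, MICE, multinomial regression and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from assistnet.associations import (
    build_analysis_table,
    compare_groups,
    fit_multinomial,
    pool_rubin,
    pooled_regression,
)
from assistnet.impute import mice_impute


# --------------------------------------------------------------------------
# descriptive comparisons


def test_identical_distributions_give_null_result():
    df = pd.DataFrame(
        {"v": ["a", "b"] * 40, "g": ["x"] * 40 + ["y"] * 40}
    )
    comp = compare_groups(df, "v", "g")
    assert comp.statistic == pytest.approx(0.0, abs=1e-12)
    assert comp.p == pytest.approx(1.0)


def test_chi_square_matches_hand_formula():
    df = pd.DataFrame(
        {
            "v": ["yes"] * 30 + ["no"] * 20 + ["yes"] * 10 + ["no"] * 40,
            "g": ["a"] * 50 + ["b"] * 50,
        }
    )
    comp = compare_groups(df, "v", "g")
    observed = np.array([[30, 20], [10, 40]])
    expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
    assert comp.test == "chi_square"
    assert comp.statistic == pytest.approx(((observed - expected) ** 2 / expected).sum())


def test_two_group_kruskal_equals_ranksum(rng):
    x = np.round(rng.normal(size=60), 1)
    y = np.round(rng.normal(0.5, size=50), 1)
    df = pd.DataFrame({"v": np.concatenate([x, y]), "g": ["a"] * 60 + ["b"] * 50})
    comp = compare_groups(df, "v", "g")
    assert comp.test == "kruskal_wallis"
    u = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
    assert comp.p == pytest.approx(u.pvalue, rel=1e-9)


def test_small_expected_counts_warn():
    df = pd.DataFrame(
        {"v": ["rare"] * 1 + ["common"] * 99, "g": ["a"] * 50 + ["b"] * 50}
    )
    comp = compare_groups(df, "v", "g")
    assert comp.warning is not None and "Fisher" in comp.warning


# --------------------------------------------------------------------------
# MICE


def _linear_table(rng, n=400):
    x = rng.normal(size=n)
    z = rng.choice(["u", "v"], size=n)
    y = 1.0 + 2.0 * x + 0.5 * (z == "v") + rng.normal(scale=1.0, size=n)
    return pd.DataFrame({"x": x, "z": z, "y": y})


def test_no_missing_returns_identical_copies(rng):
    table = _linear_table(rng)
    out = mice_impute(table, m=3, seed=0, n_iter=2)
    assert len(out) == 3
    for comp in out:
        pd.testing.assert_frame_equal(comp, table)


def test_pmm_values_come_from_observed_donors(rng):
    table = _linear_table(rng)
    miss = rng.random(len(table)) < 0.2
    table.loc[miss, "y"] = np.nan
    observed = set(table["y"].dropna())
    for comp in mice_impute(table, m=2, seed=1, n_iter=3):
        assert set(comp["y"]) <= observed


def test_mice_deterministic_and_validated(rng):
    table = _linear_table(rng)
    table.loc[:50, "x"] = np.nan
    a = mice_impute(table, m=2, seed=9, n_iter=2)
    b = mice_impute(table, m=2, seed=9, n_iter=2)
    for ca, cb in zip(a, b):
        pd.testing.assert_frame_equal(ca, cb)
    with pytest.raises(ValueError, match="at least two"):
        mice_impute(table, m=1, seed=0)
    bad = table.copy()
    bad["const"] = 1.0
    bad.loc[0, "const"] = np.nan
    with pytest.raises(ValueError, match="const"):
        mice_impute(bad, m=2, seed=0)


def test_mcar_pooled_slope_within_full_data_ci(rng):
    table = _linear_table(rng, n=500)
    X = sm.add_constant(np.column_stack([table["x"], table["z"] == "v"]).astype(float))
    full = sm.OLS(table["y"], X).fit()
    lo, hi = full.conf_int().iloc[1]
    damaged = table.copy()
    mask = rng.random((len(table), 2)) < 0.10
    damaged.loc[mask[:, 0], "x"] = np.nan
    damaged.loc[mask[:, 1], "y"] = np.nan
    fits = []
    for comp in mice_impute(damaged, m=5, seed=3, n_iter=5):
        Xc = sm.add_constant(
            np.column_stack([comp["x"], comp["z"] == "v"]).astype(float)
        )
        f = sm.OLS(comp["y"].astype(float), Xc).fit()
        names = ["const", "x", "zv"]
        fits.append(
            (
                pd.Series(f.params.to_numpy(), index=names),
                pd.DataFrame(f.cov_params().to_numpy(), index=names, columns=names),
            )
        )
    pooled = {e.term: e for e in pool_rubin(fits, n_obs=len(table))}
    # pool_rubin reports exp(estimate); compare on the log/linear scale
    assert lo <= pooled["x"].estimate <= hi


# --------------------------------------------------------------------------
# multinomial regression


def test_binary_reduction_matches_logit(rng):
    n = 500
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
    y = np.where(rng.random(n) < p, "case", "none")
    design = pd.DataFrame({"x": x})
    params, cov = fit_multinomial(design, pd.Series(y), reference="none")
    logit = sm.Logit((y == "case").astype(int), sm.add_constant(x)).fit(disp=0)
    assert params["case|const"] == pytest.approx(logit.params[0], abs=1e-8)
    assert params["case|x"] == pytest.approx(logit.params[1], abs=1e-8)
    assert cov.loc["case|x", "case|x"] == pytest.approx(logit.cov_params()[1][1], rel=1e-6)


def test_saturated_rrr_equals_cross_product_ratios(rng):
    n = 3000
    x = rng.random(n) < 0.4
    probs = np.where(x[:, None], [[0.2, 0.5, 0.3]], [[0.5, 0.3, 0.2]])
    u = rng.random(n)
    codes = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    y = np.array(["none", "g1", "g2"])[codes]
    design = pd.DataFrame({"x": x.astype(float)})
    params, _ = fit_multinomial(design, pd.Series(y), reference="none")
    tab = pd.crosstab(pd.Series(y), pd.Series(x))
    for g in ("g1", "g2"):
        cross = (tab.loc[g, True] * tab.loc["none", False]) / (
            tab.loc[g, False] * tab.loc["none", True]
        )
        assert np.exp(params[f"{g}|x"]) == pytest.approx(cross, rel=1e-6)


def test_separation_raises(rng):
    x = np.concatenate([np.zeros(50), np.ones(50)])
    y = np.where(x > 0, "case", "none")
    with pytest.raises(ValueError, match="separation"):
        fit_multinomial(pd.DataFrame({"x": x}), pd.Series(y), reference="none")


def test_null_predictor_type_i_error(rng):
    hits = 0
    for _ in range(40):
        x = rng.normal(size=800)
        y = rng.choice(["none", "a", "b"], size=800)
        params, cov = fit_multinomial(pd.DataFrame({"x": x}), pd.Series(y))
        for g in ("a", "b"):
            z = params[f"{g}|x"] / np.sqrt(cov.loc[f"{g}|x", f"{g}|x"])
            hits += abs(z) > stats.norm.ppf(0.975)
    assert hits / 80 < 0.12


# --------------------------------------------------------------------------
# Rubin pooling


def _toy_fit(est, var):
    idx = ["g|x"]
    return pd.Series([est], index=idx), pd.DataFrame([[var]], index=idx, columns=idx)


def test_pooling_identical_fits_has_no_between_variance():
    fits = [_toy_fit(0.7, 0.04)] * 3
    (eff,) = pool_rubin(fits)
    assert eff.estimate == pytest.approx(0.7)
    assert eff.between_var == pytest.approx(0.0, abs=1e-16)
    assert eff.rrr == pytest.approx(np.exp(0.7))


def test_pooling_matches_hand_computation():
    fits = [_toy_fit(1.0, 0.04), _toy_fit(1.2, 0.04), _toy_fit(1.4, 0.04)]
    (eff,) = pool_rubin(fits)
    b = np.var([1.0, 1.2, 1.4], ddof=1)
    T = 0.04 + (1 + 1 / 3) * b
    assert eff.estimate == pytest.approx(1.2)
    assert eff.between_var == pytest.approx(b)
    assert eff.within_var + (1 + 1 / 3) * eff.between_var == pytest.approx(T)
    df_expected = (3 - 1) * (T / ((1 + 1 / 3) * b)) ** 2
    assert eff.df == pytest.approx(df_expected)


def test_ci_widens_with_between_variance():
    widths = []
    for spread in (0.0, 0.1, 0.2, 0.4):
        fits = [_toy_fit(1.2 - spread, 0.04), _toy_fit(1.2, 0.04), _toy_fit(1.2 + spread, 0.04)]
        (eff,) = pool_rubin(fits)
        widths.append(np.log(eff.ci_high) - np.log(eff.ci_low))
    assert all(b > a for a, b in zip(widths, widths[1:]))


def test_mismatched_terms_rejected():
    a = _toy_fit(1.0, 0.04)
    idx = ["g|y"]
    b = (pd.Series([1.0], index=idx), pd.DataFrame([[0.04]], index=idx, columns=idx))
    with pytest.raises(ValueError, match="mismatched"):
        pool_rubin([a, b])


# --------------------------------------------------------------------------
# end-to-end pooled regression


def test_zero_missing_mi_equals_complete_fit(rng):
    from assistnet.instrument import assign_group, dichotomize_items
    from assistnet.synthetic import generate_cohort, paper_like_config

    cfg = paper_like_config(
        n=700, seed=50, missing_rate=0.0, assist_section_missing_rate=0.0
    )
    coh = generate_cohort(cfg)
    group = assign_group(dichotomize_items(coh))
    analysis = build_analysis_table(coh, group)
    pooled = pooled_regression(analysis, m=3, seed=1, n_iter=2)
    covars = analysis.drop(columns=["group"])
    outcome = pd.Series(
        pd.Categorical(analysis["group"].astype(object)), index=analysis.index
    )
    zs = tuple(c for c in ("phq9", "gad7", "rrs10", "psqi", "cas", "pq16") if c in covars)
    params, _ = fit_multinomial(covars, outcome, reference="none", zscore=zs)
    merged = pooled.set_index(pooled["outcome"] + "|" + pooled["term"])
    for name, val in params.items():
        assert merged.loc[name, "estimate"] == pytest.approx(val, abs=1e-12)
        assert merged.loc[name, "between_var"] == pytest.approx(0.0, abs=1e-16)
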