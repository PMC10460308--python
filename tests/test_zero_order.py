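"""Tetrachoric estimation, Fisher filtering and MDS layout."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from assistnet.zero_order import (
    WeightedNetwork,
    build_zero_order_network,
    fisher_exact,
    mds_layout,
    tetrachoric,
)


def oracle_tetrachoric(table: np.ndarray) -> float:
    """Grid-search + quadrature oracle for the two-step tetrachoric MLE.

    The bivariate-normal orthant probability is computed by 1-D numerical
    integration of phi(x) * Phi((tau2 - rho x) / sqrt(1 - rho^2)), fully
    independent of the implementation's closed-form bivariate CDF.
    """
    cells = np.asarray(table, dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    n = cells.sum()
    tau1 = stats.norm.ppf(1 - cells[0].sum() / n)
    tau2 = stats.norm.ppf(1 - cells[:, 0].sum() / n)

    def p11(rho):
        f = lambda x: stats.norm.pdf(x) * stats.norm.cdf(
            (tau2 - rho * x) / np.sqrt(1 - rho**2), loc=0
        )
        val, _ = integrate.quad(f, tau1, 9.0, epsabs=1e-12, epsrel=1e-10)
        return stats.norm.sf(tau1) - val  # P(Z1>tau1) - P(Z1>tau1, Z2<tau2)

    def nll(rho):
        a = p11(rho)
        p1 = stats.norm.sf(tau1)
        p2 = stats.norm.sf(tau2)
        probs = np.clip([a, p1 - a, p2 - a, 1 - p1 - p2 + a], 1e-12, None)
        c = [cells[0, 0], cells[0, 1], cells[1, 0], cells[1, 1]]
        return -float(np.dot(c, np.log(probs)))

    grid = np.linspace(-0.99, 0.99, 199)
    best = grid[np.argmin([nll(r) for r in grid])]
    res = optimize.minimize_scalar(
        nll, bounds=(max(best - 0.02, -0.9999), min(best + 0.02, 0.9999)),
        method="bounded", options={"xatol": 1e-10},
    )
    return float(res.x)


def oracle_fisher(table: np.ndarray) -> float:
    """Full hypergeometric enumeration with the point-probability rule."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = stats.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def test_independence_table_gives_zero():
    assert tetrachoric([[25, 25], [25, 25]]).r_t == pytest.approx(0.0, abs=1e-6)


def test_column_swap_negates_estimate():
    t = np.array([[40, 10], [10, 40]])
    assert tetrachoric(t).r_t == pytest.approx(-tetrachoric(t[:, ::-1]).r_t, abs=1e-6)


def test_sign_matches_cross_product():
    for table in ([[40, 10], [10, 40]], [[5, 30], [30, 5]], [[20, 8], [5, 30]]):
        est = tetrachoric(table)
        t = np.asarray(table, dtype=float)
        assert np.sign(est.r_t) == np.sign(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0])


def test_tetrachoric_matches_quadrature_oracle():
    est = tetrachoric([[40, 10], [10, 40]])
    assert est.r_t == pytest.approx(oracle_tetrachoric([[40, 10], [10, 40]]), abs=1e-4)


def test_continuity_correction_keeps_thresholds_finite():
    est = tetrachoric([[30, 0], [10, 20]])
    assert np.isfinite(est.r_t) and np.isfinite(est.tau_row) and np.isfinite(est.tau_col)


def test_tetrachoric_rejects_tiny_tables():
    with pytest.raises(ValueError, match="at least 4"):
        tetrachoric([[1, 0], [0, 1]])


@pytest.mark.parametrize(
    "table,expected",
    [([[5, 5], [5, 5]], 1.0), ([[10, 0], [10, 0]], 1.0)],
)
def test_fisher_trivial_cases(table, expected):
    assert fisher_exact(table) == pytest.approx(expected)


def test_fisher_matches_enumeration():
    for table in ([[8, 2], [1, 9]], [[12, 3], [7, 8]], [[2, 9], [8, 1]]):
        assert fisher_exact(table) == pytest.approx(oracle_fisher(table), rel=1e-9)


def test_network_weights_match_pairwise_tetrachoric(rng):
    z = rng.multivariate_normal([0, 0, 0], [[1, 0.5, 0.2], [0.5, 1, 0.1], [0.2, 0.1, 1]], 600)
    ind = pd.DataFrame((z > 0.2), columns=list("abc")).astype("boolean")
    ind.iloc[:40, 0] = pd.NA  # exercise pairwise-complete deletion
    net = build_zero_order_network(ind)
    for i, j in itertools.combinations(range(3), 2):
        keep = ind.iloc[:, i].notna() & ind.iloc[:, j].notna()
        x = ind.loc[keep].iloc[:, i].astype(bool).to_numpy()
        y = ind.loc[keep].iloc[:, j].astype(bool).to_numpy()
        tab = [
            [int((x & y).sum()), int((x & ~y).sum())],
            [int((~x & y).sum()), int((~x & ~y).sum())],
        ]
        assert net.weights[i, j] == pytest.approx(tetrachoric(tab).r_t, abs=1e-10)
    assert np.isclose(
        net.mean_weight, np.mean(net.weights[np.triu_indices(3, 1)])
    )


def test_constant_columns_dropped(rng):
    ind = pd.DataFrame(
        {
            "a": rng.random(100) > 0.5,
            "b": rng.random(100) > 0.5,
            "c": np.zeros(100, dtype=bool),
        }
    ).astype("boolean")
    net = build_zero_order_network(ind)
    assert net.labels == ["a", "b"]
    with pytest.raises(ValueError, match="at least two"):
        build_zero_order_network(ind[["a", "c"]])


def test_display_mask_uses_fisher_threshold(rng):
    x = rng.random(400) > 0.5
    y = x ^ (rng.random(400) > 0.9)  # strongly associated
    z = rng.random(400) > 0.5  # independent
    ind = pd.DataFrame({"x": x, "y": y, "z": z}).astype("boolean")
    net = build_zero_order_network(ind)
    assert net.mask[0, 1]
    ij = {tuple(sorted((net.labels.index("x"), net.labels.index("z"))))}
    for i, j in ij:
        assert net.pvalues[i, j] == pytest.approx(
            fisher_exact(
                [
                    [int((x & z).sum()), int((x & ~z).sum())],
                    [int((~x & z).sum()), int((~x & ~z).sum())],
                ]
            )
        )


def _net_from_weights(W):
    W = np.asarray(W, dtype=float)
    labels = [f"n{i}" for i in range(len(W))]
    return WeightedNetwork(labels, W, np.ones_like(W, dtype=bool))


def test_mds_equal_dissimilarities_give_equilateral_triangle():
    W = np.full((3, 3), 0.5)
    np.fill_diagonal(W, 0.0)
    layout = mds_layout(_net_from_weights(W))
    d = [
        np.linalg.norm(layout.coords[i] - layout.coords[j])
        for i, j in itertools.combinations(range(3), 2)
    ]
    assert np.ptp(d) < 1e-8
    assert layout.stress < 1e-8


def test_mds_recovers_exact_embedding(rng):
    pts = rng.random((6, 2))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    W = 1.0 - D**2 / 2.0  # invert the dissimilarity transform
    layout = mds_layout(_net_from_weights(W))
    assert layout.stress < 1e-6


def test_mds_stress_matches_recomputation(rng):
    W = rng.uniform(-0.5, 0.9, size=(7, 7))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    net = _net_from_weights(W)
    layout = mds_layout(net)
    iu = np.triu_indices(7, 1)
    D = np.sqrt(2 * (1 - W))[iu]
    dist = np.linalg.norm(
        layout.coords[:, None] - layout.coords[None, :], axis=-1
    )[iu]
    from sklearn.isotonic import IsotonicRegression

    disp = IsotonicRegression(increasing=True).fit(D, dist).predict(D)
    expected = np.sqrt(np.sum((dist - disp) ** 2) / np.sum(dist**2))
    assert layout.stress == pytest.approx(expected, abs=1e-12)


def test_mds_majorization_never_increases_stress(rng):
    W = rng.uniform(-0.8, 0.8, size=(9, 9))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    _, trace = mds_layout(_net_from_weights(W), return_trace=True)
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_mds_rejects_nonfinite_dissimilarity():
    W = np.array([[0.0, np.nan], [np.nan, 0.0]])
    net = WeightedNetwork(["a", "b"], W, np.ones((2, 2), dtype=bool))
    with pytest.raises(ValueError, match="non-finite"):
        mds_layout(net)
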