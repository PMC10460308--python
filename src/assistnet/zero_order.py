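"""Zero-order association network of dichotomised use/harm indicators.

Pairwise association between binary indicators is measured by the
tetrachoric correlation: the correlation of a latent bivariate normal
inferred from the 2x2 table, estimated in two steps (thresholds from the
margins, then 1-D likelihood maximisation in rho).  Edges are displayed when
a two-sided Fisher exact test gives p below the display threshold, and the
network is laid out by non-metric multidimensional scaling so that shorter
distances encode stronger associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = [
    "TetrachoricEstimate",
    "WeightedNetwork",
    "MdsLayout",
    "tetrachoric",
    "fisher_exact",
    "build_zero_order_network",
    "mds_layout",
]


@dataclass
class TetrachoricEstimate:
    """Two-step tetrachoric correlation estimate for a 2x2 table.

    ``table`` rows index the first variable (yes/no), columns the second, so
    ``table[0, 0]`` counts joint occurrence.  ``tau_row``/``tau_col`` are the
    standard-normal thresholds implied by the (continuity-corrected) margins.
    """

    r_t: float
    tau_row: float
    tau_col: float
    table: np.ndarray
    p_fisher: float
    reason: str | None = None  # set when the estimate is undefined


@dataclass
class WeightedNetwork:
    """Node-labelled symmetric weighted network with a display mask."""

    labels: list[str]
    weights: np.ndarray  # symmetric, zero diagonal
    mask: np.ndarray  # symmetric bool; True = edge displayed
    pvalues: np.ndarray | None = None
    mean_weight: float | None = None  # mean off-diagonal weight over estimable pairs
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape[0] != w.shape[1] or not np.allclose(w, w.T, equal_nan=True):
            raise ValueError("weight matrix must be square and symmetric")
        self.weights = w
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def displayed_weights(self) -> np.ndarray:
        """Weights with non-displayed edges zeroed."""
        return np.where(self.mask, self.weights, 0.0)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "node_i": self.labels[i],
                        "node_j": self.labels[j],
                        "weight": self.weights[i, j],
                        "p": None if self.pvalues is None else self.pvalues[i, j],
                        "displayed": bool(self.mask[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class MdsLayout:
    labels: list[str]
    coords: np.ndarray  # (n, 2)
    stress: float  # Kruskal stress-1
    n_iter: int
    seed: int | None = None


def _bvn_upper(tau1: float, tau2: float, rho: float) -> float:
    """P(Z1 > tau1, Z2 > tau2) under a standard bivariate normal with corr rho."""
    cdf = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf
    # survival via inclusion-exclusion on the joint CDF
    return 1.0 - stats.norm.cdf(tau1) - stats.norm.cdf(tau2) + cdf([tau1, tau2])


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value (point-probability rule) for a 2x2 table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be a 2x2 array of non-negative counts")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def tetrachoric(table: np.ndarray) -> TetrachoricEstimate:
    """Estimate the tetrachoric correlation of a 2x2 contingency table.

    Two-step estimator: thresholds are fixed at the standard-normal quantiles
    of the margins, then rho maximises the multinomial likelihood of the four
    cells under the bivariate-normal orthant probabilities.  When any cell is
    zero, 0.5 is added to every cell (continuity correction) so thresholds
    stay finite.
    """
    raw = np.asarray(table, dtype=float)
    if raw.shape != (2, 2) or (raw < 0).any():
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if raw.sum() < 4:
        raise ValueError("tetrachoric estimation requires a total count of at least 4")
    p_fisher = fisher_exact(np.round(raw).astype(int))
    cells = raw + 0.5 if (raw == 0).any() else raw.copy()
    n = cells.sum()
    p_row = cells[0].sum() / n  # P(first variable = yes)
    p_col = cells[:, 0].sum() / n
    if min(p_row, p_col) <= 0 or max(p_row, p_col) >= 1:
        return TetrachoricEstimate(
            np.nan, np.nan, np.nan, raw, p_fisher, reason="degenerate margin"
        )
    tau_row = stats.norm.ppf(1.0 - p_row)
    tau_col = stats.norm.ppf(1.0 - p_col)

    def negloglik(rho: float) -> float:
        p11 = _bvn_upper(tau_row, tau_col, rho)
        p1_ = 1.0 - stats.norm.cdf(tau_row)
        p_1 = 1.0 - stats.norm.cdf(tau_col)
        p10 = p1_ - p11
        p01 = p_1 - p11
        p00 = 1.0 - p1_ - p01
        probs = np.clip([p11, p10, p01, p00], 1e-12, None)
        counts = np.array([cells[0, 0], cells[0, 1], cells[1, 0], cells[1, 1]])
        return -float(counts @ np.log(probs))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-0.9999, 0.9999), method="bounded",
        options={"xatol": 1e-10},
    )
    return TetrachoricEstimate(float(res.x), tau_row, tau_col, raw, p_fisher)


def _pair_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2x2 counts from two boolean arrays (no missing values)."""
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return np.array([[a, b], [c, d]])


def build_zero_order_network(
    indicators: pd.DataFrame, alpha: float = 0.05
) -> WeightedNetwork:
    """Build the zero-order tetrachoric network from binary indicator columns.

    Uses pairwise-complete observations.  Constant columns (over their
    non-missing rows) cannot yield a tetrachoric estimate and are dropped
    with a warning.  The display mask is True where the two-sided Fisher
    exact p-value is below ``alpha``.
    """
    cols = []
    for c in indicators.columns:
        vals = indicators[c].dropna()
        if vals.nunique() < 2:
            logger.warning("dropping constant indicator column %r", c)
            continue
        cols.append(c)
    if len(cols) < 2:
        raise ValueError("need at least two non-constant indicator columns")
    p = len(cols)
    weights = np.zeros((p, p))
    pvals = np.ones((p, p))
    mask = np.zeros((p, p), dtype=bool)
    estimable = []
    for i in range(p):
        for j in range(i + 1, p):
            xi = indicators[cols[i]]
            xj = indicators[cols[j]]
            keep = xi.notna() & xj.notna()
            if keep.sum() < 4:
                weights[i, j] = weights[j, i] = np.nan
                continue
            tab = _pair_table(
                xi[keep].astype(bool).to_numpy(), xj[keep].astype(bool).to_numpy()
            )
            est = tetrachoric(tab)
            weights[i, j] = weights[j, i] = est.r_t
            pvals[i, j] = pvals[j, i] = est.p_fisher
            if np.isfinite(est.r_t):
                estimable.append(est.r_t)
            mask[i, j] = mask[j, i] = est.p_fisher < alpha
    mean_w = float(np.mean(estimable)) if estimable else np.nan
    return WeightedNetwork(
        labels=cols,
        weights=weights,
        mask=mask,
        pvalues=pvals,
        mean_weight=mean_w,
        meta={"alpha": alpha, "missing_handling": "pairwise-complete"},
    )


def _classical_mds(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:ndim]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def mds_layout(
    net: WeightedNetwork,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-12,
    return_trace: bool = False,
):
    """Non-metric (ordinal) MDS layout of a weighted network.

    Dissimilarities are ``sqrt(2 * (1 - w))`` so strongly associated nodes sit
    close together.  Minimises Kruskal stress-1 by iterative majorisation
    (SMACOF with monotone-regression disparities) from a classical-scaling
    start; the procedure is deterministic, ``seed`` is recorded for
    provenance only.
    """
    W = net.weights
    if not np.isfinite(W[~np.eye(net.n_nodes, dtype=bool)]).all():
        bad = [
            (net.labels[i], net.labels[j])
            for i in range(net.n_nodes)
            for j in range(i + 1, net.n_nodes)
            if not np.isfinite(W[i, j])
        ]
        raise ValueError(f"non-finite dissimilarities for pairs: {bad}")
    n = net.n_nodes
    D = np.sqrt(np.clip(2.0 * (1.0 - W), 0.0, None))
    np.fill_diagonal(D, 0.0)
    iu = np.triu_indices(n, 1)
    dvec = D[iu]
    X = _classical_mds(D)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def distances(X: np.ndarray) -> np.ndarray:
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(-1))[iu]

    prev_sigma = np.inf
    stress_trace: list[float] = []
    disp = dvec
    it = 0
    for it in range(1, max_iter + 1):
        dist = distances(X)
        disp = iso.fit(dvec, dist).predict(dvec)
        sigma = float(np.sum((dist - disp) ** 2))
        stress_trace.append(_stress1(dist, disp))
        if prev_sigma - sigma < tol:
            break
        prev_sigma = sigma
        # Guttman transform with disparities
        safe = np.where(dist > 0, dist, 1.0)
        ratio = np.zeros((n, n))
        ratio[iu] = disp / safe
        ratio = ratio + ratio.T
        Bmat = -ratio
        np.fill_diagonal(Bmat, ratio.sum(axis=1))
        X = (Bmat @ X) / n
    dist = distances(X)
    disp = iso.fit(dvec, dist).predict(dvec)
    layout = MdsLayout(
        labels=list(net.labels),
        coords=X,
        stress=_stress1(dist, disp),
        n_iter=it,
        seed=seed,
    )
    if return_trace:
        return layout, stress_trace
    return layout
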