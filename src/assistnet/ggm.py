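"""Gaussian graphical model estimation for the partial-correlation network.

The involvement-score network is estimated in two stages, mirroring common
psychometric-network practice: a graphical-lasso regularisation path scored
by the extended BIC picks a starting graph, and an unregularised stepwise
search (single-edge additions/removals, each refit by zero-constrained
maximum likelihood) polishes it.  The final model is always an unregularised
fit, so reported edge weights are plain partial correlations, not shrunken
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .zero_order import WeightedNetwork

__all__ = [
    "PrecisionModel",
    "glasso",
    "constrained_mle",
    "stepwise_select",
    "partial_correlations",
    "fit_ggm",
]

EdgeSet = frozenset[tuple[int, int]]


def all_pairs(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


@dataclass
class PrecisionModel:
    """A fitted Gaussian precision matrix with its graph and fit statistics."""

    omega: np.ndarray
    edge_set: EdgeSet
    r_p: np.ndarray
    log_likelihood: float
    bic: float
    n: int
    lam: float = 0.0
    gamma: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.omega.shape[0]


def _loglik(omega: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    p = omega.shape[0]
    return 0.5 * n * (logdet - float(np.sum(S * omega)) - p * np.log(2 * np.pi))


def ebic(loglik: float, n_edges: int, p: int, n: int, gamma: float) -> float:
    """Extended BIC: -2 loglik + k ln n + 4 gamma |E| ln p, k = p + |E|."""
    k = p + n_edges
    return -2.0 * loglik + k * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def _edges_of(omega: np.ndarray, atol: float = 1e-10) -> EdgeSet:
    p = omega.shape[0]
    return frozenset((i, j) for i, j in all_pairs(p) if abs(omega[i, j]) > atol)


def partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Partial correlations -w_ij / sqrt(w_ii w_jj) from a precision matrix."""
    d = np.sqrt(np.diag(omega))
    rp = -omega / np.outer(d, d)
    np.fill_diagonal(rp, 1.0)
    return rp


def _model_from_omega(
    omega: np.ndarray, S: np.ndarray, n: int, lam: float, gamma: float, **meta
) -> PrecisionModel:
    edges = _edges_of(omega)
    ll = _loglik(omega, S, n)
    return PrecisionModel(
        omega=omega,
        edge_set=edges,
        r_p=partial_correlations(omega),
        log_likelihood=ll,
        bic=ebic(ll, len(edges), omega.shape[0], n, gamma),
        n=n,
        lam=lam,
        gamma=gamma,
        meta=meta,
    )


def glasso(
    S: np.ndarray,
    lam: float,
    n: int = 1,
    gamma: float = 0.0,
    tol: float = 1e-14,
    max_iter: int = 2000,
    kkt_tol: float = 1e-6,
) -> PrecisionModel:
    """L1-penalised precision estimation (off-diagonal penalty lambda).

    Maximises ``log det(Omega) - tr(S Omega) - lam * sum_{i!=j} |omega_ij|``.
    ``lam = 0`` returns the unpenalised MLE (inverse of S).  The KKT
    conditions of the penalised problem are verified to ``kkt_tol``.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        omega = np.linalg.inv(S)
        return _model_from_omega(omega, S, n, 0.0, gamma)
    with warnings.catch_warnings():
        # at tol near machine precision sklearn can report a (converged)
        # negative dual gap as a ConvergenceWarning
        warnings.simplefilter("ignore")
        _, omega = _sk_graphical_lasso(
            S, alpha=lam, tol=tol, enet_tol=tol, max_iter=max_iter
        )
    # KKT residual: gradient of the smooth part is S - Omega^{-1}
    G = S - np.linalg.inv(omega)
    off = ~np.eye(S.shape[0], dtype=bool)
    nz = off & (np.abs(omega) > 1e-10)
    z = off & ~nz
    resid = 0.0
    if nz.any():
        resid = max(resid, float(np.abs(G[nz] + lam * np.sign(omega[nz])).max()))
    if z.any():
        resid = max(resid, float(np.clip(np.abs(G[z]) - lam, 0, None).max()))
    if resid > kkt_tol:
        raise RuntimeError(f"graphical lasso did not converge: KKT residual {resid:.2e}")
    return _model_from_omega(omega, S, n, lam, gamma, kkt_residual=resid)


def constrained_mle(
    S: np.ndarray,
    edge_set: EdgeSet | set | list,
    n: int = 1,
    gamma: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 5000,
    omega0: np.ndarray | None = None,
) -> PrecisionModel:
    """Gaussian MLE with precision entries fixed at zero off the edge set.

    Solved by iterative proportional scaling over edge cliques: each update
    adjusts a 2x2 (or 1x1) block of Omega so the fitted covariance matches S
    on that clique.  At convergence the fitted covariance equals S on the
    diagonal and on every edge pair.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    edges = sorted(tuple(sorted(e)) for e in edge_set)
    if len(edges) == len(all_pairs(p)):
        return _model_from_omega(np.linalg.inv(S), S, n, 0.0, gamma)
    if omega0 is not None:
        omega = omega0.copy()
        keep0 = np.zeros((p, p), dtype=bool)
        np.fill_diagonal(keep0, True)
        for i, j in edges:
            keep0[i, j] = keep0[j, i] = True
        omega[~keep0] = 0.0
        if np.linalg.eigvalsh(omega).min() <= 0:
            omega = np.diag(1.0 / np.diag(S))
    else:
        omega = np.diag(1.0 / np.diag(S))
    if not edges:
        return _model_from_omega(np.diag(1.0 / np.diag(S)), S, n, 0.0, gamma)
    dev = np.inf
    for _ in range(max_iter):
        for i, j in edges:
            sigma = np.linalg.inv(omega)
            idx = np.ix_([i, j], [i, j])
            omega[idx] += np.linalg.inv(S[idx]) - np.linalg.inv(sigma[idx])
        sigma = np.linalg.inv(omega)
        # touch isolated-node diagonals too
        for i in range(p):
            omega[i, i] += 1.0 / S[i, i] - 1.0 / sigma[i, i]
        sigma = np.linalg.inv(omega)
        dev = max(
            float(np.abs(np.diag(sigma) - np.diag(S)).max()),
            max((abs(sigma[i, j] - S[i, j]) for i, j in edges), default=0.0),
        )
        if dev < tol:
            break
    else:
        raise RuntimeError(
            f"iterative proportional scaling stalled; last deviation {dev:.2e}"
        )
    # exact zeros off the edge set
    keep = np.zeros((p, p), dtype=bool)
    np.fill_diagonal(keep, True)
    for i, j in edges:
        keep[i, j] = keep[j, i] = True
    omega[~keep] = 0.0
    return _model_from_omega(omega, S, n, 0.0, gamma)


def lambda_path(S: np.ndarray, n_points: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from lambda_max (empty off-diagonal) downwards."""
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * ratio, n_points)


def stepwise_select(
    S: np.ndarray,
    n: int,
    gamma: float = 0.0,
    gamma_path: float = 0.5,
    n_lambdas: int = 100,
    tie_tol: float = 1e-9,
) -> PrecisionModel:
    """Select a GGM by EBIC: glasso-path start, then greedy single-edge search.

    The EBIC(``gamma_path``)-best graph along a ``n_lambdas``-point glasso
    path (each candidate graph refit unregularised) seeds a greedy search
    over single-edge additions and removals scored by EBIC(``gamma``); the
    best strictly-improving move is accepted until none exists.  Ties within
    ``tie_tol`` prefer removals, then lexicographic edge order.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if n <= p:
        raise ValueError("stepwise selection requires n > p")
    cache: dict[EdgeSet, PrecisionModel] = {}

    def refit(edges: EdgeSet, omega0=None, g=gamma) -> PrecisionModel:
        if edges in cache:
            m = cache[edges]
        else:
            m = constrained_mle(S, edges, n=n, gamma=g, omega0=omega0)
            cache[edges] = m
        return m

    # stage 1: glasso path, EBIC(gamma_path) over distinct graphs
    best_start: PrecisionModel | None = None
    seen: set[EdgeSet] = set()
    ebic_trace = []
    for lam in lambda_path(S, n_points=n_lambdas):
        # the path only proposes candidate graphs (each refit exactly by
        # proportional scaling below), so a looser solve suffices here
        gm = glasso(S, lam, n=n, tol=1e-9, kkt_tol=1e-3)
        edges = gm.edge_set
        if edges in seen:
            continue
        seen.add(edges)
        m = refit(edges, omega0=gm.omega)
        score = ebic(m.log_likelihood, len(m.edge_set), p, n, gamma_path)
        ebic_trace.append({"lambda": float(lam), "n_edges": len(edges), "ebic": score})
        if best_start is None or score < best_start.meta["path_ebic"] - tie_tol:
            best_start = PrecisionModel(
                **{**m.__dict__, "meta": {**m.meta, "path_ebic": score}}
            )
    assert best_start is not None
    current = refit(best_start.edge_set)
    current_ebic = ebic(current.log_likelihood, len(current.edge_set), p, n, gamma)

    # stage 2: greedy single-edge moves under EBIC(gamma)
    while True:
        best_move = None  # (ebic, is_addition, edge, model)
        for i, j in all_pairs(p):
            e = (i, j)
            is_add = e not in current.edge_set
            edges = (
                current.edge_set | {e} if is_add else current.edge_set - {e}
            )
            m = refit(frozenset(edges), omega0=None)
            score = ebic(m.log_likelihood, len(m.edge_set), p, n, gamma)
            if best_move is None or score < best_move[0] - tie_tol or (
                abs(score - best_move[0]) <= tie_tol
                and (int(is_add), e) < (int(best_move[1]), best_move[2])
            ):
                best_move = (score, is_add, e, m)
        if best_move is None or best_move[0] >= current_ebic - tie_tol:
            break
        current, current_ebic = best_move[3], best_move[0]
    final = PrecisionModel(
        omega=current.omega,
        edge_set=current.edge_set,
        r_p=current.r_p,
        log_likelihood=current.log_likelihood,
        bic=current_ebic,
        n=n,
        lam=0.0,
        gamma=gamma,
        meta={
            "gamma_path": gamma_path,
            "start_edges": sorted(best_start.edge_set),
            "start_ebic": float(
                ebic(best_start.log_likelihood, len(best_start.edge_set), p, n, gamma)
            ),
            "ebic_trace": ebic_trace,
        },
    )
    return final


def fit_ggm(
    logscores: pd.DataFrame,
    gamma: float = 0.0,
    gamma_path: float = 0.5,
    n_lambdas: int = 100,
) -> tuple[PrecisionModel, WeightedNetwork]:
    """Fit the partial-correlation network of log involvement scores.

    Complete cases only; the covariance uses the maximum-likelihood
    denominator ``n``.  Returns the selected precision model and the
    corresponding weighted network (edge mask = selected edges).
    """
    data = logscores.dropna()
    n = len(data)
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        const = [c for c, s in zip(data.columns, sd) if s == 0]
        raise ValueError(f"constant score columns: {const}")
    S = np.corrcoef(X.T)
    model = stepwise_select(S, n=n, gamma=gamma, gamma_path=gamma_path, n_lambdas=n_lambdas)
    rp = model.r_p.copy()
    np.fill_diagonal(rp, 0.0)
    mask = np.zeros_like(rp, dtype=bool)
    for i, j in model.edge_set:
        mask[i, j] = mask[j, i] = True
    net = WeightedNetwork(
        labels=list(data.columns),
        weights=rp,
        mask=mask,
        mean_weight=float(rp[np.triu_indices(len(rp), 1)].mean()),
        meta={"n": n, "gamma": gamma, "gamma_path": gamma_path},
    )
    return model, net
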