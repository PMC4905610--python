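"""Lasso-regularized partial-correlation (Gaussian graphical model) networks.

The trait and its representative features are modelled jointly as a
multivariate Gaussian. The precision matrix Omega is estimated by
L1-penalized maximum likelihood (graphical lasso); full-order partial
correlations follow as

    rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj),

i.e. the correlation between variables i and j after removing their linear
dependence on all other included variables. Unlike marginal correlation,
this distinguishes direct from indirect association: in a chain
X -> Y -> Z the X-Z partial correlation vanishes. The penalty lambda is
selected by EBIC (default) or K-fold cross-validated predictive likelihood,
and is reported in the network metadata because the edge set depends on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import empirical_covariance, graphical_lasso
from sklearn.model_selection import KFold

from .datasets import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "PrecisionEstimate",
    "standardize",
    "fit_graphical_lasso",
    "select_penalty",
    "precision_to_partial",
    "build_network",
    "export_network",
    "read_network",
    "plot_network",
]

#: Partial correlations with absolute value at or below this are not edges.
ZERO_TOL = 1e-8

NODE_LAYERS = ("trait", "gene", "lc", "gc", "protein")


@dataclass
class PrecisionEstimate:
    variables: list[str]
    precision: np.ndarray  # symmetric positive-definite
    covariance: np.ndarray
    penalty: float
    criterion: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        P = self.precision
        if not np.allclose(P, P.T, atol=1e-8):
            raise ValueError("precision matrix is not symmetric")
        eig = np.linalg.eigvalsh((P + P.T) / 2)
        if eig.min() <= 0:
            raise ValueError("precision matrix is not positive definite")


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to variance 1 (population
    variance, so the empirical covariance of the result is the correlation
    matrix)."""
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [str(data.columns[i]) for i in bad]
        raise DegenerateInputError(f"constant variable(s): {names}")
    out = (arr - arr.mean(axis=0)) / sd
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def fit_graphical_lasso(
    data: pd.DataFrame, penalty: float, max_iter: int = 500, tol: float = 1e-4
) -> PrecisionEstimate:
    """L1-penalized Gaussian maximum-likelihood precision estimate.

    Maximizes ``log det(Omega) - tr(S Omega) - penalty * sum_{i!=j}
    |Omega_ij|`` where S is the empirical covariance of the (standardized)
    data. ``penalty = 0`` gives the unpenalized estimate, the inverse of S
    (requires n > p).
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    n, p = data.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    S = empirical_covariance(data.to_numpy(dtype=float), assume_centered=False)
    if penalty == 0:
        cond = np.linalg.cond(S)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"sample covariance is singular (cond={cond:.2e}); use penalty > 0"
            )
        precision = np.linalg.inv(S)
        cov = S
    else:
        try:
            cov, precision = graphical_lasso(S, alpha=penalty, max_iter=max_iter, tol=tol)
        except FloatingPointError as exc:  # pragma: no cover - solver diagnostics
            raise RuntimeError(
                f"graphical lasso did not converge at penalty={penalty} "
                f"(max_iter={max_iter}): {exc}"
            ) from exc
    precision = (precision + precision.T) / 2
    return PrecisionEstimate(list(map(str, data.columns)), precision, cov, float(penalty))


def _gaussian_loglik(S: np.ndarray, precision: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ precision))


def _edge_count(precision: np.ndarray, tol: float = ZERO_TOL) -> int:
    off = precision[np.triu_indices_from(precision, k=1)]
    return int(np.sum(np.abs(off) > tol))


def _constrained_mle(S: np.ndarray, adj: np.ndarray, max_iter: int = 200,
                     tol: float = 1e-8) -> np.ndarray:
    """Gaussian MLE of the precision matrix constrained to a given edge set
    (covariance selection), via cyclic regression updates on the fitted
    covariance. Used to score candidate supports for EBIC."""
    p = S.shape[0]
    W = S.copy()
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = np.array([i for i in range(p) if i != j])
            nb = idx[adj[idx, j]]
            w12 = np.zeros(p - 1)
            if nb.size:
                beta = np.linalg.solve(W[np.ix_(nb, nb)], S[nb, j])
                w12 = W[np.ix_(idx, nb)] @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if np.abs(W - W_old).max() < tol:
            break
    precision = np.linalg.inv(W)
    mask = ~adj
    np.fill_diagonal(mask, False)
    precision[mask] = 0.0
    return (precision + precision.T) / 2


def select_penalty(
    data: pd.DataFrame,
    criterion: str = "ebic",
    grid: Sequence[float] | None = None,
    seed: int = 0,
    ebic_gamma: float = 0.5,
    n_folds: int = 5,
) -> tuple[float, pd.DataFrame]:
    """Choose the lasso penalty from a grid.

    ``ebic`` minimizes the extended BIC,
    ``-2 loglik + E log n + 4 gamma E log p`` with E the edge count, where
    the likelihood is that of the unpenalized MLE constrained to the
    support the lasso selected at that penalty (scoring the shrunk
    estimate itself would bias selection toward small penalties);
    ``cv`` minimizes K-fold predictive negative log-likelihood. Returns the
    selected penalty and the full score table.
    """
    if criterion not in {"ebic", "cv"}:
        raise ValueError("criterion must be 'ebic' or 'cv'")
    if grid is None:
        grid = np.geomspace(0.01, 1.0, 15)
    grid = sorted(float(g) for g in grid)
    if len(grid) == 0:
        raise ValueError("penalty grid is empty")
    n, p = data.shape
    arr = data.to_numpy(dtype=float)
    rows = []
    for lam in grid:
        try:
            if criterion == "ebic":
                est = fit_graphical_lasso(data, lam)
                S = empirical_covariance(arr, assume_centered=False)
                adj = np.abs(est.precision) > ZERO_TOL
                np.fill_diagonal(adj, True)
                refit = _constrained_mle(S, adj)
                ll = _gaussian_loglik(S, refit, n)
                E = _edge_count(est.precision)
                score = -2 * ll + E * np.log(n) + 4 * ebic_gamma * E * np.log(p)
                rows.append((lam, score, E))
            else:
                kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
                neg_ll = 0.0
                E_total = 0
                for train, test in kf.split(arr):
                    est = fit_graphical_lasso(data.iloc[train], lam)
                    S_test = empirical_covariance(arr[test], assume_centered=False)
                    neg_ll -= _gaussian_loglik(S_test, est.precision, len(test))
                    E_total += _edge_count(est.precision)
                rows.append((lam, neg_ll, E_total / n_folds))
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.warning("penalty %.4g failed: %s", lam, exc)
            rows.append((lam, np.inf, np.nan))
    table = pd.DataFrame(rows, columns=["penalty", "score", "n_edges"])
    if not np.isfinite(table["score"]).any():
        raise RuntimeError("every penalty in the grid failed to fit")
    best = float(table.loc[table["score"].idxmin(), "penalty"])
    logger.info("selected penalty %.4g by %s", best, criterion)
    return best, table


def precision_to_partial(precision: np.ndarray) -> np.ndarray:
    """Partial correlations ``rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)``
    with unit diagonal."""
    precision = np.asarray(precision, dtype=float)
    d = np.diag(precision)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    denom = np.sqrt(np.outer(d, d))
    rho = -precision / denom
    np.fill_diagonal(rho, 1.0)
    return rho


def build_network(
    rho: np.ndarray,
    nodes: Sequence[tuple[str, str]],
    zero_tol: float = ZERO_TOL,
    penalty: float | None = None,
) -> nx.Graph:
    """Signed weighted graph from a partial-correlation matrix.

    ``nodes`` is a sequence of (node_id, layer) with layer one of
    trait/gene/lc/gc/protein (used for rendering). An edge exists iff
    ``|rho_ij| > zero_tol``; its sign annotates positive vs negative
    partial correlation (solid vs dotted lines in figures).
    """
    rho = np.asarray(rho, dtype=float)
    k = rho.shape[0]
    if len(nodes) != k:
        raise ValueError("node metadata length does not match matrix")
    G = nx.Graph()
    if penalty is not None:
        G.graph["penalty"] = float(penalty)
    for node_id, layer in nodes:
        G.add_node(str(node_id), layer=str(layer))
    ids = [str(n) for n, _ in nodes]
    for i in range(k):
        for j in range(i + 1, k):
            val = rho[i, j]
            if abs(val) > zero_tol:
                G.add_edge(ids[i], ids[j], weight=float(val),
                           sign="+" if val > 0 else "-")
    return G


def export_network(G: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML (node ``layer``, edge ``weight``/``sign``
    attributes) or as an edge-list TSV (source, target, pcorr, sign)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "edge_tsv":
        rows = [
            {"source": u, "target": v, "pcorr": d["weight"], "sign": d["sign"]}
            for u, v, d in G.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "pcorr", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'graphml' or 'edge_tsv'")
    return path


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        G = nx.read_graphml(path)
        return nx.relabel_nodes(G, str)
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        G = nx.Graph()
        for _, row in df.iterrows():
            G.add_edge(str(row["source"]), str(row["target"]),
                       weight=float(row["pcorr"]), sign=str(row["sign"]))
        return G
    raise ValueError(f"unknown format {fmt!r}")


def plot_network(G: nx.Graph, path: str | Path, seed: int = 0) -> Path:
    """Static rendering: solid lines for positive, dotted for negative
    partial correlations; node colour by layer."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {"trait": "gold", "gene": "firebrick", "lc": "black",
               "gc": "purple", "protein": "forestgreen"}
    pos = nx.spring_layout(G, seed=seed)
    fig, ax = plt.subplots(figsize=(7, 7))
    colors = [palette.get(G.nodes[n].get("layer", ""), "lightgray") for n in G.nodes]
    nx.draw_networkx_nodes(G, pos, node_color=colors, node_size=600, ax=ax)
    nx.draw_networkx_labels(G, pos, font_size=7, font_color="white", ax=ax)
    pos_edges = [(u, v) for u, v, d in G.edges(data=True) if d["weight"] > 0]
    neg_edges = [(u, v) for u, v, d in G.edges(data=True) if d["weight"] <= 0]
    nx.draw_networkx_edges(G, pos, edgelist=pos_edges, style="solid", ax=ax)
    nx.draw_networkx_edges(G, pos, edgelist=neg_edges, style="dotted", ax=ax)
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
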