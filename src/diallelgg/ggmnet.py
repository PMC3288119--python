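"""Shrinkage graphical-Gaussian co-expression network inference.

The gene-gene dependency graph is estimated from expression residuals in
three steps:

1. **Shrinkage partial correlations.**  The sample correlation matrix R is
   shrunk toward the identity, ``R* = (1 - lambda) R + lambda I``, with the
   analytic optimal intensity ``lambda = sum Var(r_ij) / sum r_ij^2`` over
   the off-diagonal entries (clipped to [0, 1]).  Partial correlations come
   from the scaled negative inverse, ``pcor_ij = -w_ij / sqrt(w_ii w_jj)``
   with ``W = (R*)^-1``.  Shrinkage keeps the estimate positive definite
   when genes outnumber samples.
2. **Edge probabilities.**  Off-diagonal partial correlations are modeled
   as a two-component mixture ``f(r) = eta0 f0(r; kappa) + (1 - eta0) fA(r)``
   where ``f0(r; kappa) ~ (1 - r^2)^((kappa - 3)/2)`` is the null density of
   a correlation coefficient with ``kappa`` degrees of freedom and ``fA`` is
   a flat alternative.  ``kappa`` and ``eta0`` are fit by maximum likelihood
   (grid over kappa, EM for eta0).  The posterior probability that an edge
   is real is one minus the local false discovery rate,
   ``1 - eta0 f0(r)/f(r)``.
3. **Thresholding.**  Edges with probability >= 0.80 (inclusive) form the
   network; isolated genes stay in the node list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "GgmNetwork",
    "shrinkage_partial_correlation",
    "edge_probabilities",
    "fit_null_mixture",
    "build_network",
    "EDGE_PROBABILITY_CUTOFF",
]

EDGE_PROBABILITY_CUTOFF = 0.80


def shrinkage_partial_correlation(residuals) -> Tuple[pd.DataFrame, float]:
    """Shrinkage partial-correlation matrix and the shrinkage intensity.

    ``residuals`` is an individuals x genes matrix (DataFrame or ndarray)
    with n >= 3 rows and >= 2 non-constant columns.
    """
    X = residuals.to_numpy(dtype=float) if hasattr(residuals, "to_numpy") else \
        np.asarray(residuals, dtype=float)
    genes = list(residuals.columns) if hasattr(residuals, "columns") else \
        [f"g{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("need >= 3 individuals")
    if p < 2:
        raise ValueError("need >= 2 genes")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [genes[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant gene column(s): {bad[:5]}")
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / (n - 1)

    # analytic optimal shrinkage toward the identity (off-diagonals only);
    # Var(r_ij) from the moments of w_kij = z_ki z_kj without materializing
    # the n x p x p product array
    wbar = (Z.T @ Z) / n
    w2sum = (Z ** 2).T @ (Z ** 2)
    var_r = (n / (n - 1) ** 3) * (w2sum - n * wbar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))

    R_star = (1.0 - lam) * R
    np.fill_diagonal(R_star, 1.0)
    omega = np.linalg.inv(R_star)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2.0
    return pd.DataFrame(pcor, index=genes, columns=genes), lam


def _log_f0(r: np.ndarray, kappa: float) -> np.ndarray:
    """log null density of a correlation coefficient with kappa df."""
    return ((kappa - 3.0) / 2.0) * np.log1p(-r ** 2) - \
        special.betaln(0.5, (kappa - 1.0) / 2.0)


def _mixture_ll(r: np.ndarray, kappa: float, n_em: int) -> Tuple[float, float]:
    """EM for the null proportion at fixed kappa; returns (loglik, eta0)."""
    lf0 = _log_f0(r, kappa)
    f0 = np.exp(lf0)
    eta0 = 0.9
    for _ in range(n_em):
        num = eta0 * f0
        gamma = num / (num + (1 - eta0) * 0.5)
        new = float(gamma.mean())
        if abs(new - eta0) < 1e-9:
            eta0 = new
            break
        eta0 = new
    eta0 = min(eta0, 1.0 - 1e-12)
    ll = float(np.log(eta0 * f0 + (1 - eta0) * 0.5).sum())
    return ll, eta0


def fit_null_mixture(r: np.ndarray, kappa_grid: Optional[np.ndarray] = None,
                     n_em: int = 50) -> Tuple[float, float]:
    """ML fit of (eta0, kappa) for the null component of the pcor mixture.

    Coarse-then-refined grid search over kappa; at each kappa the null
    proportion eta0 is optimized by EM against a flat alternative density
    on (-1, 1).
    """
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-10, 1 - 1e-10)
    if kappa_grid is None:
        kappa_grid = np.geomspace(4.0, 1e5, 40)
    best = (-np.inf, 1.0, float(kappa_grid[0]))
    for kappa in kappa_grid:
        ll, eta0 = _mixture_ll(r, float(kappa), n_em)
        if ll > best[0]:
            best = (ll, eta0, float(kappa))
    # refine around the coarse optimum
    k0 = best[2]
    for kappa in np.geomspace(k0 / 2.5, k0 * 2.5, 25):
        ll, eta0 = _mixture_ll(r, float(kappa), n_em)
        if ll > best[0]:
            best = (ll, eta0, float(kappa))
    _, eta0, kappa = best
    return eta0, kappa


def edge_probabilities(pcor: pd.DataFrame) -> pd.DataFrame:
    """Posterior edge probabilities (1 - local fdr) for every gene pair."""
    P = pcor.to_numpy(dtype=float)
    p = P.shape[0]
    iu = np.triu_indices(p, k=1)
    r = P[iu]
    if r.size < 50:
        raise ValueError("fewer than 50 off-diagonal values; mixture unidentifiable")
    if not np.all(np.isfinite(r)) or np.any(np.abs(r) >= 1):
        raise ValueError("off-diagonal partial correlations must be finite in (-1, 1)")
    eta0, kappa = fit_null_mixture(r)
    f0 = np.exp(_log_f0(np.clip(r, -1 + 1e-10, 1 - 1e-10), kappa))
    f = eta0 * f0 + (1 - eta0) * 0.5
    prob = np.clip(1.0 - eta0 * f0 / f, 0.0, 1.0)
    out = np.zeros((p, p))
    out[iu] = prob
    out = out + out.T
    res = pd.DataFrame(out, index=pcor.index, columns=pcor.columns)
    res.attrs["eta0"] = eta0
    res.attrs["kappa"] = kappa
    return res


@dataclass
class GgmNetwork:
    """Thresholded co-expression network with per-edge statistics."""

    nodes: List[str]
    pcor: pd.DataFrame
    probability: pd.DataFrame
    shrinkage_lambda: float
    cutoff: float = EDGE_PROBABILITY_CUTOFF
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, e in self.edges.iterrows():
            g.add_edge(e["gene_a"], e["gene_b"], weight=float(e["pcor"]),
                       probability=float(e["probability"]))
        return g

    def to_edgelist_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_pajek(self, path) -> None:
        """Pajek NET export: nodes plus undirected pcor-weighted edges."""
        import networkx as nx

        g = self.to_networkx()
        for _u, _v, data in g.edges(data=True):  # pajek wants strings
            data["probability"] = f"{data['probability']:.4f}"
        nx.write_pajek(g, path)


def build_network(pcor: pd.DataFrame, probability: Optional[pd.DataFrame] = None,
                  cutoff: float = EDGE_PROBABILITY_CUTOFF,
                  shrinkage_lambda: float = float("nan")) -> GgmNetwork:
    """Undirected edge set {(i, j): probability >= cutoff} (inclusive)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    if probability is None:
        probability = edge_probabilities(pcor)
    genes = list(pcor.index)
    P = probability.to_numpy(dtype=float)
    C = pcor.to_numpy(dtype=float)
    iu = np.triu_indices(len(genes), k=1)
    keep = P[iu] >= cutoff
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[0][keep]],
            "gene_b": [genes[j] for j in iu[1][keep]],
            "pcor": C[iu][keep],
            "probability": P[iu][keep],
        }
    )
    return GgmNetwork(genes, pcor, probability, shrinkage_lambda, cutoff, edges)
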