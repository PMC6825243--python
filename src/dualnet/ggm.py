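"""Shrinkage-based Gaussian graphical model inference with an exact edge test.

With more genes than samples the sample correlation matrix is singular, so
partial correlations are computed from a shrunk estimate
``R(lambda) = (1 - lambda) R + lambda I`` with the analytic optimal
shrinkage intensity. Shrinkage compresses the null distribution of the
resulting partial correlations onto ``[-(1 - lambda), 1 - lambda]``: under
the null hypothesis of no partial correlation the scaled square
``(r / (1 - lambda))^2`` follows a Beta(1/2, (kappa - 1)/2) law, where
kappa is an effective degrees-of-freedom parameter. Because the nominal
value ``n - 1 - (p - 2)`` is negative when p >> n, kappa is fitted by
maximum likelihood over all edges under a predominantly-null assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .core import ExpressionMatrix, bh_adjust, standardize_genes

__all__ = [
    "ShrunkGGM",
    "GeneNetwork",
    "estimate_lambda",
    "shrunk_correlation",
    "partial_correlations",
    "estimate_kappa",
    "edge_pvalue",
    "infer_network",
]


@dataclass
class ShrunkGGM:
    """A fitted shrinkage GGM: lambda, kappa, partial correlations, edge tests."""

    gene_ids: list[str]
    lambda_: float
    kappa: float
    n_samples: int
    pcor: np.ndarray
    edge_table: pd.DataFrame  # gene_a, gene_b, pcor, p, q (lexicographic pairs)


@dataclass
class GeneNetwork:
    """Edges surviving the FDR threshold, over the full node universe."""

    nodes: list[str]
    edges: pd.DataFrame  # gene_a, gene_b, pcor, q
    threshold: float

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {
            (a, b) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])
        }

    @property
    def connected_genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, pcor=row.pcor, q=row.q)
        return g


def estimate_lambda(x: np.ndarray) -> float:
    """Analytic optimal intensity for shrinking the correlation matrix to I.

    ``x`` is a samples x genes matrix with standardized columns. The
    optimum is ``sum_{i!=j} Var(r_ij) / sum_{i!=j} r_ij^2`` with
    ``Var(r_ij) = n/(n-1)^3 * sum_k (w_kij - wbar_ij)^2`` and
    ``w_kij = x_ki x_kj``; the result is clipped to [0, 1]. A zero
    denominator (all sample correlations zero) maps to full shrinkage.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("at least 3 samples are required to estimate lambda")
    r = x.T @ x / (n - 1)
    wbar = r * (n - 1) / n
    s2 = (x**2).T @ (x**2)  # sum_k w_kij^2
    var_r = n / (n - 1) ** 3 * (s2 - n * wbar**2)
    mask = ~np.eye(p, dtype=bool)
    denom = float(np.sum(r[mask] ** 2))
    numer = float(np.sum(var_r[mask]))
    if denom == 0.0:
        return 1.0
    return float(np.clip(numer / denom, 0.0, 1.0))


def shrunk_correlation(r: np.ndarray, lambda_: float) -> np.ndarray:
    """Convex combination ``(1 - lambda) r + lambda I``."""
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    r = np.asarray(r, dtype=float)
    return (1.0 - lambda_) * r + lambda_ * np.eye(r.shape[0])


def partial_correlations(r_shrunk: np.ndarray) -> np.ndarray:
    """Partial correlations from the (positive-definite) shrunk correlation.

    ``pcor_ij = -omega_ij / sqrt(omega_ii omega_jj)`` with
    ``Omega = R(lambda)^-1``; the diagonal is reported as 1 by convention
    but is never tested.
    """
    r_shrunk = np.asarray(r_shrunk, dtype=float)
    try:
        cho = linalg.cho_factor(r_shrunk)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "shrunk correlation matrix is not positive definite; "
            "use a shrinkage intensity lambda > 0"
        ) from exc
    omega = linalg.cho_solve(cho, np.eye(r_shrunk.shape[0]))
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2.0
    np.fill_diagonal(pcor, 1.0)
    return pcor


def _null_neg_loglik(kappa: float, log1mu2: np.ndarray, m: int) -> float:
    # density of u = r/(1-lambda): f(u) = (1-u^2)^((kappa-3)/2) / B(1/2,(kappa-1)/2)
    return -(
        (kappa - 3.0) / 2.0 * float(np.sum(log1mu2))
        - m * float(special.betaln(0.5, (kappa - 1.0) / 2.0))
    )


def estimate_kappa(
    pcor_offdiagonals: np.ndarray,
    lambda_: float,
    mode: str | float = "fit",
    n_samples: int | None = None,
) -> float:
    """Effective degrees of freedom of the null edge distribution.

    ``mode="fit"`` maximizes the null log-likelihood of the scaled Beta
    density over ``kappa in (3, 10 n]``, assuming the edge population is
    predominantly null; a numeric mode is returned as-is.
    """
    if not isinstance(mode, str):
        return float(mode)
    if mode != "fit":
        raise ValueError(f"unknown kappa mode {mode!r}")
    if not 0.0 <= lambda_ < 1.0:
        raise ValueError("kappa fitting requires lambda in [0, 1)")
    r = np.asarray(pcor_offdiagonals, dtype=float)
    if r.size < 30:
        raise ValueError("at least 30 off-diagonal partial correlations are required")
    if n_samples is None:
        raise ValueError("n_samples is required in fit mode (sets the upper bound)")
    u2 = np.clip((r / (1.0 - lambda_)) ** 2, 0.0, 1.0 - 1e-12)
    log1mu2 = np.log1p(-u2)
    upper = 10.0 * n_samples
    res = optimize.minimize_scalar(
        _null_neg_loglik,
        args=(log1mu2, r.size),
        bounds=(3.0 + 1e-6, upper),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(f"kappa likelihood optimization failed: {res.message}")
    kappa = float(res.x)
    if kappa > upper - 1e-3:
        warnings.warn(
            f"kappa hit the upper bound {upper:g}; the edge population may be "
            "degenerate (all partial correlations near zero)",
            stacklevel=2,
        )
    return kappa


def edge_pvalue(r, lambda_: float, kappa: float):
    """Exact two-sided p-value for a shrunk partial correlation.

    Under the null, ``(r/(1-lambda))^2 ~ Beta(1/2, (kappa-1)/2)``; the
    p-value is the upper tail of that Beta at the observed scaled square.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if kappa <= 3:
        raise ValueError("kappa must exceed 3")
    scale = 1.0 - lambda_
    if scale <= 0:
        raise ValueError("lambda must be < 1 for edge testing")
    if np.any(np.abs(r) > scale * (1 + 1e-12)):
        raise ValueError("|partial correlation| exceeds 1 - lambda")
    u2 = np.clip((r / scale) ** 2, 0.0, 1.0)
    p = stats.beta.sf(u2, 0.5, (kappa - 1.0) / 2.0)
    return p if p.ndim else float(p)


def infer_network(
    matrix: ExpressionMatrix,
    threshold: float = 0.01,
    kappa: str | float = "fit",
) -> tuple[ShrunkGGM, GeneNetwork]:
    """Full pipeline: lambda, shrunk partial correlations, edge test, FDR network.

    The input is standardized per gene (a no-op on already-standardized
    data); all p(p-1)/2 unordered pairs are tested and BH-adjusted; the
    network keeps edges with ``q <= threshold``.
    """
    matrix = standardize_genes(matrix)
    x = matrix.values.T  # samples x genes
    n, p = x.shape
    lam = estimate_lambda(x)
    r = x.T @ x / (n - 1)
    np.fill_diagonal(r, 1.0)
    pcor = partial_correlations(shrunk_correlation(r, lam))
    iu, ju = np.triu_indices(p, k=1)
    r_off = pcor[iu, ju]
    kap = estimate_kappa(r_off, lam, mode=kappa, n_samples=n)
    pvals = edge_pvalue(r_off, lam, kap)
    qvals = bh_adjust(pvals)
    genes = matrix.gene_ids
    # lexicographically sorted endpoints for deterministic output
    pairs = [tuple(sorted((genes[i], genes[j]))) for i, j in zip(iu, ju)]
    gene_a = [a for a, _ in pairs]
    gene_b = [b for _, b in pairs]
    edge_table = pd.DataFrame(
        {"gene_a": gene_a, "gene_b": gene_b, "pcor": r_off, "p": pvals, "q": qvals}
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    ggm = ShrunkGGM(genes, lam, kap, n, pcor, edge_table)
    kept = edge_table[edge_table["q"] <= threshold]
    network = GeneNetwork(list(genes), kept[["gene_a", "gene_b", "pcor", "q"]].reset_index(drop=True), threshold)
    return ggm, network
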