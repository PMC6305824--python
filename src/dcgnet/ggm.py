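"""Shrinkage Gaussian graphical model inference for one condition.

The sample correlation matrix R is shrunk toward the identity with the
analytic intensity

    lambda* = sum_{i<j} Var_hat(r_ij) / sum_{i<j} r_ij**2,   clipped to [0, 1],

where ``Var_hat(r_ij)`` is the unbiased empirical variance of the per-sample
cross-products of the standardized data.  Partial correlations follow from
the inverse of the shrunk matrix, rho_ij = -omega_ij / sqrt(omega_ii *
omega_jj), and edges are ranked by |rho| with a lexicographic tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "PartialCorrelationModel",
    "sample_correlation",
    "shrinkage_lambda",
    "shrink_correlation",
    "partial_correlations",
    "rank_edges",
    "top_k_edges",
    "fit_ggm",
]

logger = logging.getLogger(__name__)

TOP_EDGES_DEFAULT = 1500

EDGE_COLUMNS = ["gene_i", "gene_j", "pcor", "rank"]


@dataclass(frozen=True)
class PartialCorrelationModel:
    gene_ids: tuple[str, ...]
    lambda_star: float
    shrunk_correlation: np.ndarray
    partial_correlation: np.ndarray
    edges: pd.DataFrame  # ranked, columns gene_i, gene_j, pcor, rank
    n_samples: int


def _as_matrix(study_slice) -> np.ndarray:
    x = np.asarray(study_slice, dtype=float)
    if x.ndim != 2:
        raise DataError("expected a genes x samples matrix")
    return x


def _gene_labels(study_slice, p: int) -> list[str]:
    if isinstance(study_slice, pd.DataFrame):
        return [str(g) for g in study_slice.index]
    return [f"v{i}" for i in range(p)]


def _standardize(x: np.ndarray, labels) -> np.ndarray:
    """Center and scale each gene across samples (sd with ddof=1)."""
    sd = x.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataError(f"zero-variance gene(s): {[labels[i] for i in zero]}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def sample_correlation(study_slice) -> np.ndarray:
    """Pearson correlation across samples; unit diagonal, symmetric."""
    x = _as_matrix(study_slice)
    if x.shape[1] < 3:
        raise DataError("need >= 3 samples to estimate correlations")
    z = _standardize(x, _gene_labels(study_slice, x.shape[0]))
    n = x.shape[1]
    r = (z @ z.T) / (n - 1)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def shrinkage_lambda(study_slice) -> float:
    """Analytic shrinkage intensity toward the identity target.

    A degenerate denominator (all off-diagonal correlations zero) yields 1 by
    convention; the result is always clipped to [0, 1].
    """
    x = _as_matrix(study_slice)
    n = x.shape[1]
    if n < 3:
        raise DataError("need >= 3 samples (variance of r undefined below that)")
    z = _standardize(x, _gene_labels(study_slice, x.shape[0]))

    # w_kij = z_ik z_jk; wbar its sample mean; r_ij = n/(n-1) * wbar_ij
    wbar = (z @ z.T) / n
    wsq = (z**2) @ (z**2).T  # sum_k w_kij^2
    r = wbar * n / (n - 1)
    var_r = n / (n - 1) ** 3 * (wsq - n * wbar**2)

    iu = np.triu_indices_from(r, k=1)
    denom = float(np.sum(r[iu] ** 2))
    if denom == 0.0:
        return 1.0
    lam = float(np.sum(var_r[iu])) / denom
    return float(np.clip(lam, 0.0, 1.0))


def shrink_correlation(r: np.ndarray, lam: float) -> np.ndarray:
    """(1 - lambda) * R + lambda * I, elementwise."""
    if not 0.0 <= lam <= 1.0:
        raise ParameterError("lambda must lie in [0, 1]")
    return (1.0 - lam) * r + lam * np.eye(r.shape[0])


def partial_correlations(shrunk_correlation: np.ndarray) -> np.ndarray:
    """Partial correlations from the inverse of a (shrunk) correlation matrix."""
    s = np.asarray(shrunk_correlation, dtype=float)
    try:
        omega = np.linalg.inv(s)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"correlation matrix is numerically singular: {exc}") from exc
    d = np.sqrt(np.diag(omega))
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise DataError("inverse correlation has non-positive diagonal; matrix not PD")
    rho = -omega / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def rank_edges(partial_correlation: np.ndarray, gene_ids) -> pd.DataFrame:
    """All i<j pairs sorted by |pcor| descending; ties broken lexicographically."""
    rho = np.asarray(partial_correlation, dtype=float)
    genes = [str(g) for g in gene_ids]
    if rho.shape != (len(genes), len(genes)):
        raise ParameterError("matrix shape does not match gene_ids")
    iu, ju = np.triu_indices(len(genes), k=1)
    records = sorted(
        ((genes[i], genes[j], rho[i, j]) if genes[i] <= genes[j] else (genes[j], genes[i], rho[i, j])
         for i, j in zip(iu, ju)),
        key=lambda rec: (-abs(rec[2]), rec[0], rec[1]),
    )
    edges = pd.DataFrame(records, columns=["gene_i", "gene_j", "pcor"])
    edges["rank"] = np.arange(1, len(edges) + 1)
    return edges


def top_k_edges(edges: pd.DataFrame, k: int = TOP_EDGES_DEFAULT) -> pd.DataFrame:
    """First k edges of the ranked list (all of them if k exceeds the total)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > len(edges):
        logger.warning("requested %d edges but only %d available; returning all", k, len(edges))
    return edges.head(k).reset_index(drop=True)


def fit_ggm(study_slice) -> PartialCorrelationModel:
    """Full shrinkage GGM fit for one condition's genes x samples matrix."""
    x = _as_matrix(study_slice)
    genes = tuple(_gene_labels(study_slice, x.shape[0]))
    r = sample_correlation(study_slice)
    lam = shrinkage_lambda(study_slice)
    shrunk = shrink_correlation(r, lam)
    rho = partial_correlations(shrunk)
    edges = rank_edges(rho, genes)
    return PartialCorrelationModel(
        gene_ids=genes,
        lambda_star=lam,
        shrunk_correlation=shrunk,
        partial_correlation=rho,
        edges=edges,
        n_samples=x.shape[1],
    )
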