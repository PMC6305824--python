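"""Per-dataset differential expression and the multi-dataset intersection.

Fold change is defined on log2 group means (cancer minus normal, so
``fold_change = 2**log2fc``), per-gene p-values come from a two-sample Welch
t-test, and adjustment is Benjamini--Hochberg.  Thresholds are strict:
a gene is called differentially expressed when ``fold_change > fc_hi`` or
``fold_change < fc_lo`` *and* ``p_adj < alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .simulate import CANCER, NORMAL, ExpressionStudy

__all__ = [
    "MutualDegSet",
    "log2_fold_change",
    "gene_wise_test",
    "bh_adjust",
    "call_degs",
    "de_table",
    "deg_genes",
    "mutual_degs",
]

logger = logging.getLogger(__name__)

FC_HI = 2.0
FC_LO = 0.5
ALPHA = 0.01

TABLE_COLUMNS = ["gene", "log2fc", "fold_change", "p_raw", "p_adj", "is_deg"]


@dataclass(frozen=True)
class MutualDegSet:
    """Intersection of per-dataset DEG calls with per-dataset counts."""

    genes: frozenset[str]
    per_dataset_counts: dict[str, int]


def _condition_means(study: ExpressionStudy, label: str) -> pd.Series:
    block = study.slice_condition(label)
    return block.mean(axis=1)


def log2_fold_change(
    study: ExpressionStudy, cancer: str = CANCER, normal: str = NORMAL
) -> pd.Series:
    """Per-gene difference of condition means on the log2 scale (cancer - normal)."""
    return (_condition_means(study, cancer) - _condition_means(study, normal)).rename("log2fc")


def gene_wise_test(
    study: ExpressionStudy, cancer: str = CANCER, normal: str = NORMAL
) -> pd.Series:
    """Two-sided Welch t-test p-value per gene.

    Degenerate genes (zero variance in both groups) get p = 1 when the group
    means agree and p = 0 otherwise, rather than raising.
    """
    x = study.slice_condition(cancer).to_numpy(float)
    y = study.slice_condition(normal).to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]
    if min(n1, n2) < 2:
        raise DataError("Welch test needs >= 2 samples per condition")

    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = se2 == 0.0
    if degenerate.any():
        p = np.where(degenerate & (m1 == m2), 1.0, np.where(degenerate, 0.0, p))
    return pd.Series(p, index=study.values.index, name="p_raw")


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p_values must be one-dimensional")
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def call_degs(
    table: pd.DataFrame,
    fc_hi: float = FC_HI,
    fc_lo: float = FC_LO,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Flag DEGs in a table carrying ``fold_change`` and ``p_adj`` columns.

    All comparisons are strict, so a fold change of exactly ``fc_hi`` or an
    adjusted p of exactly ``alpha`` is *not* called.
    """
    if not (0 < fc_lo < 1 < fc_hi):
        raise ParameterError("thresholds must satisfy 0 < fc_lo < 1 < fc_hi")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    out = table.copy()
    fc = out["fold_change"].to_numpy(float)
    padj = out["p_adj"].to_numpy(float)
    out["is_deg"] = ((fc > fc_hi) | (fc < fc_lo)) & (padj < alpha)
    return out


def de_table(
    study: ExpressionStudy,
    fc_hi: float = FC_HI,
    fc_lo: float = FC_LO,
    alpha: float = ALPHA,
    cancer: str = CANCER,
    normal: str = NORMAL,
) -> pd.DataFrame:
    """Full per-gene differential expression table for one dataset."""
    l2fc = log2_fold_change(study, cancer=cancer, normal=normal)
    p_raw = gene_wise_test(study, cancer=cancer, normal=normal)
    table = pd.DataFrame(
        {
            "gene": study.values.index,
            "log2fc": l2fc.to_numpy(),
            "fold_change": np.exp2(l2fc.to_numpy()),
            "p_raw": p_raw.to_numpy(),
        }
    )
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    return call_degs(table, fc_hi=fc_hi, fc_lo=fc_lo, alpha=alpha)


def deg_genes(table: pd.DataFrame) -> frozenset[str]:
    return frozenset(table.loc[table["is_deg"], "gene"])


def mutual_degs(
    tables: Sequence[pd.DataFrame],
    dataset_ids: Sequence[str] | None = None,
) -> MutualDegSet:
    """Intersection of DEG calls across datasets.

    An empty intersection is valid (logged as a warning); an empty table list
    is an error.
    """
    if not tables:
        raise ParameterError("mutual_degs requires at least one table")
    ids = list(dataset_ids) if dataset_ids is not None else [f"dataset{i + 1}" for i in range(len(tables))]
    if len(ids) != len(tables):
        raise ParameterError("dataset_ids must match tables in length")
    sets = [deg_genes(t) for t in tables]
    genes = frozenset.intersection(*sets)
    if not genes:
        logger.warning("mutual DEG intersection is empty across %d datasets", len(tables))
    return MutualDegSet(
        genes=genes, per_dataset_counts={d: len(s) for d, s in zip(ids, sets)}
    )
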