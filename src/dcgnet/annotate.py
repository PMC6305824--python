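"""Characterization of a gene set: curated-list overlaps, hypergeometric
over-/under-representation against GMT collections, and TF-regulon lookup.

Gene identifiers are matched case-sensitively after whitespace stripping; no
alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import DataError, ParameterError

__all__ = [
    "GeneSetCollection",
    "RegulonRecord",
    "RegulonTable",
    "RegulatorSummary",
    "read_gmt",
    "read_gene_list",
    "read_regulons",
    "overlap_counts",
    "venn3_partition",
    "hypergeom_enrich",
    "regulators_of",
    "shared_regulators",
]

logger = logging.getLogger(__name__)

MODES = ("activation", "repression", "unknown")

_MODE_ALIASES = {
    "activation": "activation",
    "repression": "repression",
    "unknown": "unknown",
}


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, non-empty gene sets from one source (e.g. a GMT file)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: frozenset[str]) -> dict[str, frozenset[str]]:
        return {name: members & universe for name, members in self.sets.items()}


class RegulonRecord(NamedTuple):
    tf: str
    target: str
    mode: str


@dataclass(frozen=True)
class RegulonTable:
    """Deduplicated (tf, target, mode) regulatory links."""

    records: tuple[RegulonRecord, ...]

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(r.tf for r in self.records)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(r.target for r in self.records)


def _clean(token: str) -> str:
    return token.strip()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set_name TAB description TAB gene TAB gene ..."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}:{lineno}: GMT rows need name, description, >=1 gene")
        name = _clean(fields[0])
        if name in sets:
            raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = frozenset(_clean(g) for g in fields[2:] if _clean(g))
        if not genes:
            raise DataError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def read_gene_list(path) -> frozenset[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        token = _clean(line)
        if token and not token.startswith("#"):
            genes.add(token)
    return frozenset(genes)


def read_regulons(path) -> RegulonTable:
    """Read a TF TAB target TAB mode[ TAB refs...] table (TRRUST dialect).

    Malformed rows are skipped with a logged line number; duplicate triples
    are dropped.
    """
    seen: set[RegulonRecord] = set()
    records: list[RegulonRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not _clean(fields[0]) or not _clean(fields[1]):
            logger.warning("%s:%d: malformed regulon row skipped", path, lineno)
            continue
        mode = _MODE_ALIASES.get(_clean(fields[2]).lower())
        if mode is None:
            logger.warning("%s:%d: unrecognized mode %r, row skipped", path, lineno, fields[2])
            continue
        record = RegulonRecord(_clean(fields[0]), _clean(fields[1]), mode)
        if record not in seen:
            seen.add(record)
            records.append(record)
    return RegulonTable(records=tuple(records))


def overlap_counts(
    query: Iterable[str], lists: GeneSetCollection
) -> dict[str, dict]:
    """Per-list intersections with the query, with counts and query coverage."""
    q = frozenset(query)
    out = {}
    for name, members in lists.sets.items():
        inter = q & members
        out[name] = {
            "overlap": inter,
            "count": len(inter),
            "coverage": len(inter) / len(q) if q else 0.0,
        }
    return out


def venn3_partition(
    query: Iterable[str], set_a: Iterable[str], set_b: Iterable[str]
) -> dict[str, frozenset[str]]:
    """The 7 cells of the three-way Venn diagram (query, A, B)."""
    q, a, b = frozenset(query), frozenset(set_a), frozenset(set_b)
    return {
        "query_only": q - a - b,
        "a_only": a - q - b,
        "b_only": b - q - a,
        "query_a": (q & a) - b,
        "query_b": (q & b) - a,
        "a_b": (a & b) - q,
        "query_a_b": q & a & b,
    }


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-/under-representation of the query in each set.

    With M = |universe|, K = |set ∩ universe|, N = |query| and k the observed
    overlap: p_over = P[X >= k], p_under = P[X <= k].  BH q-values are
    computed across the collection for each tail.
    """
    u = frozenset(_clean(g) for g in universe)
    q = frozenset(_clean(g) for g in query)
    if not u:
        raise DataError("universe is empty")
    if not q:
        raise DataError("query is empty")
    if not q <= u:
        raise DataError(f"query genes outside universe: {sorted(q - u)[:5]} ...")

    m, n_query = len(u), len(q)
    rows = []
    for name, members in sorted(collection.restricted_to(u).items()):
        k_set = len(members)
        k_obs = len(q & members)
        dist = stats.hypergeom(m, k_set, n_query)
        rows.append(
            {
                "set_name": name,
                "set_size": k_set,
                "overlap_count": k_obs,
                "expected": n_query * k_set / m,
                "p_over": float(dist.sf(k_obs - 1)),
                "p_under": float(dist.cdf(k_obs)),
            }
        )
    table = pd.DataFrame(rows)
    table["q_over"] = bh_adjust(table["p_over"].to_numpy())
    table["q_under"] = bh_adjust(table["p_under"].to_numpy())
    return table


@dataclass(frozen=True)
class RegulatorSummary:
    """TFs per query gene and query-gene targets per TF."""

    by_gene: dict[str, frozenset[str]]
    by_tf: dict[str, frozenset[str]]
    modes: dict[tuple[str, str], frozenset[str]]

    def tf_counts(self) -> dict[str, int]:
        return {g: len(tfs) for g, tfs in self.by_gene.items()}


def regulators_of(genes: Iterable[str], regulons: RegulonTable) -> RegulatorSummary:
    """Distinct TFs regulating each query gene, and each TF's query targets."""
    q = frozenset(_clean(g) for g in genes)
    by_gene: dict[str, set[str]] = {}
    by_tf: dict[str, set[str]] = {}
    modes: dict[tuple[str, str], set[str]] = {}
    for tf, target, mode in regulons.records:
        if target in q:
            by_gene.setdefault(target, set()).add(tf)
            by_tf.setdefault(tf, set()).add(target)
            modes.setdefault((tf, target), set()).add(mode)
    return RegulatorSummary(
        by_gene={g: frozenset(v) for g, v in by_gene.items()},
        by_tf={t: frozenset(v) for t, v in by_tf.items()},
        modes={k: frozenset(v) for k, v in modes.items()},
    )


def shared_regulators(summary: RegulatorSummary, genes: Sequence[str]) -> frozenset[str]:
    """TFs regulating every one of the given genes (empty if any is unregulated)."""
    sets = [summary.by_gene.get(_clean(g), frozenset()) for g in genes]
    if not sets:
        return frozenset()
    return frozenset.intersection(*sets)
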