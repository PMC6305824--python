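"""Undirected, unweighted gene networks and exact betweenness centrality.

Betweenness is computed by Brandes' single-source accumulation and reported
unnormalized (sums of pair-path fractions over unordered pairs); the
downstream top-fraction cut depends only on ranks, which normalization cannot
change.  A normalized variant is available behind a flag.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "GeneNetwork",
    "build_graph",
    "betweenness",
    "degree_centrality",
    "rank_nodes",
    "centrality_table",
]

logger = logging.getLogger(__name__)


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneNetwork:
    """Simple undirected graph over a fixed node universe (isolates kept)."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    condition: str = ""

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise DataError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise DataError(f"edge ({a!r}, {b!r}) has endpoint outside the universe")

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {v: [] for v in self.nodes}
        for a, b in sorted(self.edges):
            adj[a].append(b)
            adj[b].append(a)
        return adj

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(
    edges: Iterable[tuple[str, str]],
    universe: Iterable[str],
    condition: str = "",
) -> GeneNetwork:
    """Simple graph over the full universe; self-loops dropped, duplicates merged."""
    nodes = tuple(dict.fromkeys(str(v) for v in universe))
    node_set = set(nodes)
    clean: set[tuple[str, str]] = set()
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            logger.warning("dropping self-loop on %r", a)
            continue
        if a not in node_set or b not in node_set:
            raise DataError(f"edge endpoint outside universe: ({a!r}, {b!r})")
        pair = _pair(a, b)
        if pair in clean:
            logger.warning("deduplicating edge %r", pair)
        clean.add(pair)
    return GeneNetwork(nodes=nodes, edges=frozenset(clean), condition=condition)


def betweenness(network: GeneNetwork, normalized: bool = False) -> dict[str, float]:
    """Exact betweenness centrality for every node (Brandes accumulation).

    Disconnected pairs contribute nothing; endpoints are not counted on their
    own paths.  With ``normalized=True`` scores are divided by
    (n-1)(n-2)/2, the number of pairs excluding the node itself.
    """
    adj = network.adjacency()
    bc = dict.fromkeys(network.nodes, 0.0)
    for s in network.nodes:
        # single-source shortest paths (BFS; unweighted graph)
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in network.nodes}
        sigma = dict.fromkeys(network.nodes, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(network.nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation
        delta = dict.fromkeys(network.nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was counted from both endpoints
    for v in bc:
        bc[v] /= 2.0
    if normalized:
        n = network.n_nodes
        scale = (n - 1) * (n - 2) / 2.0
        if scale > 0:
            bc = {v: b / scale for v, b in bc.items()}
    return bc


def degree_centrality(network: GeneNetwork) -> dict[str, int]:
    """Node degree; secondary score, not used for hub selection."""
    deg = dict.fromkeys(network.nodes, 0)
    for a, b in network.edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def rank_nodes(scores: Mapping[str, float]) -> list[str]:
    """Nodes by score descending; ties broken lexicographically by id."""
    return sorted(scores, key=lambda v: (-scores[v], v))


def centrality_table(scores: Mapping[str, float]) -> pd.DataFrame:
    """Ordered table (node, betweenness, rank) with dense ranks."""
    ordered = rank_nodes(scores)
    values = [scores[v] for v in ordered]
    ranks: list[int] = []
    rank = 0
    previous: float | None = None
    for value in values:
        if previous is None or value != previous:
            rank += 1
            previous = value
        ranks.append(rank)
    return pd.DataFrame({"node": ordered, "betweenness": values, "rank": ranks})
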