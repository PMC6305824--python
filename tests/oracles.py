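"""Independent brute-force oracles used to verify the package implementations.

Everything here is deliberately naive (loops, enumeration, closed forms) and
shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by direct definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = []
        for later_pos, later_idx in enumerate(order, start=1):
            if later_pos >= rank_pos:
                candidates.append(p[later_idx] * m / later_pos)
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def welch_p(x: list[float], y: list[float]) -> float:
    """Two-sided Welch t-test p-value from the t CDF, written from scratch."""
    from scipy.stats import t as t_dist

    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    v1 = sum((a - m1) ** 2 for a in x) / (n1 - 1)
    v2 = sum((a - m2) ** 2 for a in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * float(t_dist.sf(abs(t), df))


def betweenness_pair_enumeration(nodes, edges) -> dict:
    """Betweenness by counting shortest paths for every (s, t) pair.

    Runs a BFS from every node to get distances and path counts, then for
    each unordered pair (s, t) credits every intermediate v with
    sigma_sv * sigma_vt / sigma_st when distances are additive.  This is a
    different algorithm from Brandes' dependency accumulation.
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    dist, sigma = {}, {}
    for s in nodes:
        d = {v: math.inf for v in nodes}
        count = {v: 0.0 for v in nodes}
        d[s], count[s] = 0, 1.0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if d[w] == math.inf:
                    d[w] = d[v] + 1
                    queue.append(w)
                if d[w] == d[v] + 1:
                    count[w] += count[v]
        dist[s], sigma[s] = d, count

    bc = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1 :]:
            if dist[s][t] == math.inf:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bc


def shrinkage_lambda_loops(x: np.ndarray) -> float:
    """Analytic shrinkage intensity by explicit loops over pairs and samples."""
    p, n = x.shape
    z = np.empty_like(x, dtype=float)
    for i in range(p):
        mean = x[i].mean()
        sd = math.sqrt(sum((v - mean) ** 2 for v in x[i]) / (n - 1))
        z[i] = (x[i] - mean) / sd
    num = den = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            w = [z[i, k] * z[j, k] for k in range(n)]
            wbar = sum(w) / n
            r = wbar * n / (n - 1)
            var_r = n / (n - 1) ** 3 * sum((wk - wbar) ** 2 for wk in w)
            num += var_r
            den += r * r
    if den == 0.0:
        return 1.0
    return min(1.0, max(0.0, num / den))


def hypergeom_tail_sums(M: int, K: int, N: int, k: int) -> tuple[float, float]:
    """(P[X >= k], P[X <= k]) for X ~ hypergeometric(M, K, N) by pmf summation."""
    total = math.comb(M, N)

    def pmf(j: int) -> float:
        if j < 0 or j > K or N - j > M - K:
            return 0.0
        return math.comb(K, j) * math.comb(M - K, N - j) / total

    p_over = sum(pmf(j) for j in range(k, min(K, N) + 1))
    p_under = sum(pmf(j) for j in range(0, k + 1))
    return p_over, p_under


def partial_corr_3var(r12: float, r13: float, r23: float) -> float:
    """Closed-form rho_{12|3} for three variables."""
    return (r12 - r13 * r23) / math.sqrt((1 - r13**2) * (1 - r23**2))
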