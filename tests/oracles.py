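"""Independent brute-force reference implementations used only by tests.

Each oracle follows the plain definition of its statistic, without any
of the vectorised shortcuts the package uses, so agreement is a real
cross-check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_force_es(scores, member_flags, weight_exponent=1.0):
    """Walk the ranked list step by step; return (ES, running sums)."""
    scores = list(scores)
    n = len(scores)
    n_hits = sum(member_flags)
    assert 0 < n_hits < n
    nr = sum(abs(s) ** weight_exponent for s, m in zip(scores, member_flags) if m)
    running = []
    total = 0.0
    for s, m in zip(scores, member_flags):
        if m:
            total += abs(s) ** weight_exponent / nr
        else:
            total -= 1.0 / (n - n_hits)
        running.append(total)
    best = 0.0
    for value in running:
        if abs(value) > abs(best) or (abs(value) == abs(best) and value > best):
            best = value
    return best, running


def bh_stepup(pvalues):
    """Benjamini-Hochberg by the literal step-up definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(prev, p[i] * m / rank)
        adjusted[i] = value
        prev = value
    return adjusted


def hypergeom_tail(m_total, n_de, n_targets, k):
    """P(X >= k) for X ~ Hypergeometric(M, K, n) by full enumeration."""
    denom = math.comb(m_total, n_targets)
    total = 0
    for j in range(k, min(n_de, n_targets) + 1):
        total += math.comb(n_de, j) * math.comb(m_total - n_de, n_targets - j)
    return total / denom


def average_ranks(values):
    """Average ranks (1-based) with ties averaged, by explicit grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho: Pearson correlation of hand-computed average ranks."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)) * math.sqrt(
        sum((b - my) ** 2 for b in ry)
    )
    return num / den


def betweenness_brute(adjacency):
    """Unnormalised shortest-path betweenness by BFS path enumeration.

    ``adjacency``: dict node -> set of neighbours (undirected).  Each
    unordered pair (s, t) contributes sigma_st(v) / sigma_st once.
    """
    nodes = sorted(adjacency)
    bc = {v: 0.0 for v in nodes}
    for si, s in enumerate(nodes):
        for t in nodes[si + 1 :]:
            # enumerate all shortest s-t paths by BFS layering
            dist = {s: 0}
            queue = deque([s])
            while queue:
                u = queue.popleft()
                for w in adjacency[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        queue.append(w)
            if t not in dist:
                continue
            paths = []
            stack = [[s]]
            while stack:
                path = stack.pop()
                u = path[-1]
                if u == t:
                    paths.append(path)
                    continue
                for w in adjacency[u]:
                    if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                        stack.append(path + [w])
            sigma = len(paths)
            inner = {}
            for path in paths:
                for v in path[1:-1]:
                    inner[v] = inner.get(v, 0) + 1
            for v, count in inner.items():
                bc[v] += count / sigma
    return bc
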