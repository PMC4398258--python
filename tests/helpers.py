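"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: exact integer
combinatorics for the hypergeometric/Fisher tests and a separate, plainly
written Markov-clustering implementation for cross-checking.
"""

from math import comb

import numpy as np


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact integer enumeration."""
    k_min = max(0, n + K - N)
    k_max = min(n, K)
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(max(k, k_min), k_max + 1))
    return num / comb(N, n)


def fisher_exact_enum(a: int, b: int, c: int, d: int, rtol: float = 1e-7) -> float:
    """Two-sided Fisher p by exact enumeration over tables with fixed margins.

    Sums probabilities of tables whose pmf is <= (1 + rtol) times the
    observed pmf, with the tie comparison done in exact integer arithmetic.
    """
    N = a + b + c + d
    K = a + b
    n = a + c
    k_min = max(0, n + K - N)
    k_max = min(n, K)
    nums = {x: comb(K, x) * comb(N - K, n - x) for x in range(k_min, k_max + 1)}
    obs = nums[a]
    # integer tie rule: num_x * 10^s <= obs * (10^s + r) with rtol = r / 10^s
    scale = 10 ** 12
    r = int(round(rtol * scale))
    total = sum(v for v in nums.values() if v * scale <= obs * (scale + r))
    return total / comb(N, n)


def reference_mcl(edges, n_nodes: int, inflation: float, iters: int = 80):
    """Plain textbook MCL: square, inflate, renormalise, no pruning.

    Returns a list of frozensets (clusters over nodes 0..n_nodes-1 that have
    at least one edge); written independently of the package implementation.
    """
    M = [[0.0] * n_nodes for _ in range(n_nodes)]
    touched = set()
    for u, v, *w in edges:
        weight = w[0] if w else 1.0
        M[u][v] = weight
        M[v][u] = weight
        touched.add(u)
        touched.add(v)
    for i in range(n_nodes):
        M[i][i] = 1.0
    A = np.array(M)
    A = A / A.sum(axis=0)
    for _ in range(iters):
        A = A @ A
        A = A ** inflation
        A = A / A.sum(axis=0)
    adj = (A > 1e-6) | (A > 1e-6).T
    seen = set()
    clusters = []
    for start in sorted(touched):
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(int(v) for v in np.flatnonzero(adj[u]) if v in touched)
        seen |= comp
        clusters.append(frozenset(comp))
    return clusters


def partition_labels(truth_map, cluster_assignment):
    """Aligned (true, predicted) label lists; unassigned items get unique labels."""
    true, pred = [], []
    fresh = 10 ** 9
    for item, t_label in truth_map.items():
        p = cluster_assignment.get(item)
        if p is None:
            p = fresh
            fresh += 1
        true.append(t_label)
        pred.append(p)
    return true, pred
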