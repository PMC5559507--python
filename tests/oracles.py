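"""Independent brute-force oracles for the weighted graph measures.

Everything here is deliberately naive: shortest paths by exhaustive simple-path
enumeration, clustering by explicit triple loops, assortativity by an explicit
edge list.  These implementations share no code with mspli.graphs and serve as
the ground truth the fast implementations are checked against.
"""

from itertools import permutations

import numpy as np


def brute_shortest_paths(W):
    """All-pairs shortest path lengths by enumerating every simple path."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    nodes = range(n)
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            best = np.inf
            others = [v for v in nodes if v not in (src, dst)]
            for r in range(len(others) + 1):
                for mid in permutations(others, r):
                    path = (src,) + mid + (dst,)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if W[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / W[a, b]
                    if ok:
                        best = min(best, length)
            D[src, dst] = best
    return D


def brute_degree(W):
    n = W.shape[0]
    return np.array([sum(W[i, j] for j in range(n) if j != i) / (n - 1) for i in range(n)])


def brute_clustering(W):
    n = W.shape[0]
    ci = np.zeros(n)
    for i in range(n):
        num = 0.0
        den = 0.0
        for k in range(n):
            for l in range(n):
                if k == i or l == i or l == k:
                    continue
                num += W[i, k] * W[i, l] * W[k, l]
                den += W[i, k] * W[i, l]
        ci[i] = num / den if den > 0 else 0.0
    return ci, float(np.mean(ci))


def brute_path_length(W):
    D = brute_shortest_paths(W)
    n = W.shape[0]
    inv = []
    for i in range(n):
        for j in range(n):
            if i != j:
                inv.append(0.0 if np.isinf(D[i, j]) else 1.0 / D[i, j])
    m = np.mean(inv)
    return D, (np.inf if m == 0 else 1.0 / m)


def brute_degree_correlation(W):
    d = brute_degree(W)
    xs, ys = [], []
    n = W.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                xs.append(d[i])
                ys.append(d[j])
    if len(xs) < 4:
        return float("nan")
    xs, ys = np.array(xs), np.array(ys)
    # zero endpoint-degree variance (regular graphs) is undefined; allow for
    # float jitter from the naive summation order
    if xs.std() < 1e-12 * max(1.0, abs(xs.mean())) or ys.std() < 1e-12 * max(
        1.0, abs(ys.mean())
    ):
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def brute_degree_diversity(W):
    s = W.sum(axis=1)
    return float(np.mean(s**2) / np.mean(s))


def brute_radius_diameter(W):
    D = brute_shortest_paths(W)
    n = W.shape[0]
    ecc = [max(D[i, j] for j in range(n) if j != i) for i in range(n)]
    return float(min(ecc)), float(max(ecc))
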