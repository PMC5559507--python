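"""Weighted graph measures of the connectivity matrices.

All measures operate on a symmetric weighted adjacency matrix W (PLI values,
zero diagonal).  Conventions:

* degree of node i      : mean of W_ij over j != i
* clustering Ci         : sum_{k!=l} W_ik W_il W_kl / sum_{k!=l} W_ik W_il
  (weighted triangle intensity; Ci = 0 for nodes with < 2 nonzero links)
* edge length           : L_ij = 1 / W_ij, infinite for absent links; path
  lengths are Dijkstra shortest paths on these lengths
* average path length Lw: harmonic-mean form 1 / mean(1/L_ij) over ordered
  pairs, so disconnected pairs (1/L = 0) are handled gracefully
* Gamma / Lambda        : Cw and Lw divided by their means over surrogate
  matrices obtained by permuting the off-diagonal weights (symmetry kept)
* Rw (degree correlation): Pearson correlation of endpoint degrees over
  connected pairs, both orderings counted (standard assortativity)
* Kw (degree diversity) : <degree^2> / <degree>
* radius / diameter     : min / max node eccentricity (eccentricity = largest
  shortest-path distance from the node); infinite if disconnected
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

DEFAULT_N_SURROGATES = 50


def _check_matrix(W: np.ndarray, min_n: int = 2) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape != (n, n):
        raise ValueError("W must be square")
    if n < min_n:
        raise ValueError(f"need at least {min_n} nodes, got {n}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("diagonal must be zero")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    return W


def degree(W: np.ndarray) -> np.ndarray:
    """Per-node mean link weight."""
    W = _check_matrix(W, min_n=2)
    n = W.shape[0]
    return W.sum(axis=1) / (n - 1)


def clustering_coefficient(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted clustering coefficient per node and its mean Cw."""
    W = _check_matrix(W, min_n=3)
    num = np.diag(W @ W @ W)  # sum_{k,l} W_ik W_kl W_li; diag-zero removes k=i, l=i
    s = W.sum(axis=1)
    q = (W**2).sum(axis=1)
    denom = s**2 - q  # sum_{k != l} W_ik W_il
    ci = np.zeros_like(s)
    np.divide(num, denom, out=ci, where=denom > 0)
    return ci, float(ci.mean())


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    D = dijkstra(csr_matrix(lengths), directed=False)
    return D


def path_length(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Pairwise shortest-path distances and harmonic-mean average path length Lw."""
    W = _check_matrix(W, min_n=2)
    D = _distance_matrix(W)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(D[off]), 0.0, 1.0 / D[off])
    mean_inv = inv.mean()
    lw = np.inf if mean_inv == 0 else 1.0 / mean_inv
    return D, float(lw)


def degree_correlation(W: np.ndarray) -> float:
    """Degree assortativity Rw: Pearson correlation of connected nodes' degrees.

    Returns NaN (documented sentinel) when endpoint degrees have zero
    variance (e.g. regular graphs) or there are fewer than 2 edges.
    """
    W = _check_matrix(W, min_n=2)
    d = degree(W)
    ii, jj = np.nonzero(np.triu(W, k=1))
    if ii.size < 2:
        return float("nan")
    x = np.concatenate([d[ii], d[jj]])
    y = np.concatenate([d[jj], d[ii]])
    # near-zero endpoint-degree variance (regular graphs): undefined, never 0
    if x.std() < 1e-12 * max(1.0, abs(x.mean())):
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def degree_diversity(W: np.ndarray) -> float:
    """Kw = <s^2> / <s>, the second-to-first moment ratio of node strength.

    Strength s_i = sum_j W_ij (so s = (n-1) x mean-link-weight degree; on a
    unit-weight star over 4 nodes the strengths are {3,1,1,1} and Kw = 2).
    Kw is homogeneous of degree 1: scaling all weights by c scales Kw by c.
    """
    W = _check_matrix(W, min_n=2)
    s = W.sum(axis=1)
    if s.mean() == 0:
        raise ValueError("degree diversity undefined for an all-zero matrix")
    return float((s**2).mean() / s.mean())


def radius_diameter(W: np.ndarray) -> tuple[float, float]:
    """(radius, diameter) = (min, max) node eccentricity; (inf, inf) if disconnected."""
    W = _check_matrix(W, min_n=2)
    D = _distance_matrix(W)
    n = D.shape[0]
    ecc = np.max(np.where(np.eye(n, dtype=bool), -np.inf, D), axis=1)
    return float(ecc.min()), float(ecc.max())


def surrogate_normalize(
    W: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
) -> tuple[float, float]:
    """Normalized clustering (Gamma = Cw/Cr) and path length (Lambda = Lw/Lr).

    Surrogates permute the off-diagonal upper-triangle weights uniformly at
    random and mirror them, preserving symmetry and the weight distribution;
    Cr and Lr are the surrogate means.  With all weights equal every
    permutation is the identity matrix, so both ratios are exactly 1.
    """
    W = _check_matrix(W, min_n=4)
    _, cw = clustering_coefficient(W)
    _, lw = path_length(W)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(W.shape[0], k=1)
    weights = W[iu]
    if np.ptp(weights) == 0:
        return 1.0, 1.0  # every permutation is the identity matrix
    crs, lrs = [], []
    for _ in range(n_surrogates):
        perm = rng.permutation(weights)
        S = np.zeros_like(W)
        S[iu] = perm
        S = S + S.T
        _, c = clustering_coefficient(S)
        _, l = path_length(S)
        crs.append(c)
        lrs.append(l)
    cr = float(np.mean(crs))
    lr = float(np.mean(lrs))
    gamma = np.nan if cr == 0 else cw / cr
    lam = np.nan if lr == 0 else lw / lr
    return float(gamma), float(lam)


@dataclass
class GraphMetrics:
    """The eight subject-level graph measures (plus the per-node degree)."""

    degree: np.ndarray
    mean_degree: float
    Cw: float
    Gamma: float
    Lw: float
    Lambda: float
    Rw: float
    Kw: float
    radius: float
    diameter: float
    n_surrogates: int

    def scalars(self) -> dict[str, float]:
        return {
            "degree": self.mean_degree,
            "Cw": self.Cw,
            "Gamma": self.Gamma,
            "Lw": self.Lw,
            "Lambda": self.Lambda,
            "Rw": self.Rw,
            "Kw": self.Kw,
            "radius": self.radius,
            "diameter": self.diameter,
        }


def compute_graph_metrics(
    W: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
) -> GraphMetrics:
    """All eight measures of one connectivity matrix."""
    W = _check_matrix(W, min_n=4)
    d = degree(W)
    _, cw = clustering_coefficient(W)
    _, lw = path_length(W)
    gamma, lam = surrogate_normalize(W, n_surrogates=n_surrogates, seed=seed)
    rad, diam = radius_diameter(W)
    return GraphMetrics(
        degree=d,
        mean_degree=float(d.mean()),
        Cw=cw,
        Gamma=gamma,
        Lw=lw,
        Lambda=lam,
        Rw=degree_correlation(W),
        Kw=degree_diversity(W),
        radius=rad,
        diameter=diam,
        n_surrogates=n_surrogates,
    )
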