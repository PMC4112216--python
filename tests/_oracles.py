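"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity from first principles by a different route
than the library (triple loops, naive agglomeration, exact rational tail
sums, generalized eigenproblems, numerical integration) so agreement is a
genuine cross-check rather than a tautology.
"""

from fractions import Fraction
from math import comb, lgamma

import numpy as np
from scipy.integrate import quad


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap on an adjacency with unit diagonal."""
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = 0.0
            for u in range(n):
                if u != i and u != j:
                    l_ij += a[i, u] * a[u, j]
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
    return t


def naive_linkage(d: np.ndarray, method: str) -> list[float]:
    """O(n^3) agglomerative clustering; returns the sorted merge heights.

    Average linkage is unweighted (UPGMA): the inter-cluster distance is the
    mean over all cross pairs of the original dissimilarity.
    """
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                pairs = [d[i, j] for i in clusters[x] for j in clusters[y]]
                dist = {
                    "average": float(np.mean(pairs)),
                    "complete": float(np.max(pairs)),
                    "single": float(np.min(pairs)),
                }[method]
                if dist < best[0]:
                    best = (dist, (x, y))
        (h, (x, y)) = best
        heights.append(h)
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return sorted(heights)


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """Exact rational upper-tail P(X >= k) for Hypergeometric(N, K, n)."""
    total = comb(N, n)
    s = Fraction(0)
    for i in range(k, min(n, K) + 1):
        s += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(s)


def t_two_sided_p(t_stat: float, df: int) -> float:
    """Two-sided t tail by numerical integration of the density."""

    def pdf(x):
        logc = lgamma((df + 1) / 2) - lgamma(df / 2) - 0.5 * np.log(df * np.pi)
        return np.exp(logc - (df + 1) / 2 * np.log1p(x * x / df))

    tail, _ = quad(pdf, abs(t_stat), np.inf)
    return 2.0 * tail


def cca_first_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """First canonical correlation by the textbook generalized eigenproblem.

    Solves C_xy C_yy^{-1} C_yx a = rho^2 C_xx a on column-centered data.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    n = x.shape[0]
    cxx = xc.T @ xc / (n - 1)
    cyy = yc.T @ yc / (n - 1)
    cxy = xc.T @ yc / (n - 1)
    m = cxy @ np.linalg.solve(cyy, cxy.T)
    from scipy.linalg import eigh

    vals = eigh(m, cxx, eigvals_only=True)
    return float(np.sqrt(np.clip(vals[-1], 0.0, 1.0)))
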