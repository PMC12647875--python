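"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths of the package (and of networkx
where the package delegates to it): Floyd-Warshall all-pairs distances,
path-counting betweenness, direct triangle-formula clustering, truncated
walk-count subgraph centrality, exhaustive modularity / core-periphery
searches, and a recursive DTW path enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if m[i, j] > 0:
                d[i, j] = 1.0 / m[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_oracle(m: np.ndarray) -> float:
    d = floyd_warshall(m)
    n = m.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1) / 2)


def char_path_length_oracle(m: np.ndarray) -> float:
    d = floyd_warshall(m)
    n = m.shape[0]
    vals = [
        d[i, j]
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(d[i, j])
    ]
    return float(np.mean(vals)) if vals else float("nan")


def _count_shortest_paths(m: np.ndarray, d: np.ndarray, tol: float = 1e-10):
    """sigma[s, t] = number of shortest s-t paths, by DAG recursion."""
    n = m.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(d[s])
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            for v in range(n):
                if m[v, t] > 0 and np.isfinite(d[s, v]):
                    if abs(d[s, v] + 1.0 / m[v, t] - d[s, t]) < tol:
                        sigma[s, t] += sigma[s, v]
    return sigma


def betweenness_oracle(m: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    n = m.shape[0]
    d = floyd_warshall(m)
    sigma = _count_shortest_paths(m, d, tol)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if (
                    np.isfinite(d[s, v])
                    and np.isfinite(d[v, t])
                    and abs(d[s, v] + d[v, t] - d[s, t]) < tol
                ):
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def clustering_oracle(m: np.ndarray) -> np.ndarray:
    """Geometric-mean triangle intensity on max-normalized weights."""
    n = m.shape[0]
    w = m / m.max() if m.max() > 0 else m
    cc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(m[i])
        k = nbrs.size
        if k < 2:
            continue
        total = 0.0
        for a, b in itertools.combinations(nbrs, 2):
            if m[a, b] > 0:
                total += (w[i, a] * w[i, b] * w[a, b]) ** (1.0 / 3.0)
        cc[i] = 2.0 * total / (k * (k - 1))
    return cc


def subgraph_centrality_series_oracle(
    m: np.ndarray, k_max: int = 30
) -> np.ndarray:
    """Truncated closed-walk series sum_k (A^k)_ii / k!."""
    a = (m > 0).astype(float)
    n = a.shape[0]
    out = np.zeros(n)
    power = np.eye(n)
    fact = 1.0
    for k in range(k_max + 1):
        if k > 0:
            power = power @ a
            fact *= k
        out += np.diag(power) / fact
    return out


def modularity_oracle(m: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Direct Newman modularity with resolution gamma."""
    two_m = m.sum()
    k = m.sum(axis=1)
    q = 0.0
    n = m.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += m[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def best_bipartition_modularity(m: np.ndarray, gamma: float = 1.0) -> float:
    """Exhaustive search over all 2-group partitions (plus the trivial one)."""
    n = m.shape[0]
    best = modularity_oracle(m, np.zeros(n, dtype=int), gamma)
    for bits in range(1, 2 ** (n - 1)):
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        best = max(best, modularity_oracle(m, labels, gamma))
    return best


def core_quality_oracle(m: np.ndarray, core: np.ndarray) -> float:
    iu = np.triu_indices(m.shape[0], k=1)
    delta = (core[iu[0]] | core[iu[1]]).astype(float)
    w = m[iu]
    denom = np.linalg.norm(w) * np.linalg.norm(delta)
    return float(w @ delta / denom) if denom > 0 else 0.0


def best_core_periphery(m: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive search over all nonempty core assignments (n <= ~12)."""
    n = m.shape[0]
    best_q, best_core = -1.0, None
    for bits in range(1, 2**n):
        core = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        q = core_quality_oracle(m, core)
        if q > best_q:
            best_q, best_core = q, core
    return best_q, best_core


def dtw_oracle(a, b) -> float:
    """Minimum cumulative |a_i - b_j| over all monotone warping paths,
    by exhaustive recursion (use only for short series)."""
    a = list(map(float, a))
    b = list(map(float, b))

    def rec(i: int, j: int) -> float:
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        options = []
        if i > 0:
            options.append(rec(i - 1, j))
        if j > 0:
            options.append(rec(i, j - 1))
        if i > 0 and j > 0:
            options.append(rec(i - 1, j - 1))
        return cost + min(options)

    return rec(len(a) - 1, len(b) - 1)
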