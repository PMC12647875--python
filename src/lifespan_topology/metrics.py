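"""Weighted graph-theory metrics on normalized connectivity matrices.

Twelve organizational measures: global efficiency, characteristic path
length, small-worldness, average strength, modularity, core/periphery
structure, s-core, k-core, local efficiency, clustering coefficient,
betweenness centrality and subgraph centrality.  Conventions:

* Path-based measures use the inverse-weight length transform
  (length = 1/w), the standard choice for weighted distance metrics on
  connectivity data.
* Weighted clustering uses the geometric-mean (Onnela) triangle
  intensity on max-normalized weights.
* Disconnected pairs contribute 0 to efficiency; characteristic path
  length averages finite distances only and flags disconnection.
* Small-worldness is the null-normalized sigma
  (C/<C_null>) / (L/<L_null>) over degree- and weight-preserving
  rewired networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path
from scipy.stats import ks_2samp

from lifespan_topology.preprocess import compute_density, validate_matrix

logger = logging.getLogger(__name__)

#: The 12 organizational measures, in reporting order.
ALL_METRICS = [
    "global_efficiency",
    "char_path_length",
    "small_worldness",
    "avg_strength",
    "modularity",
    "core_periphery",
    "s_core",
    "k_core",
    "local_efficiency",
    "clustering",
    "betweenness",
    "subgraph_centrality",
]

#: Metrics retained for the manifold stage (k-core excluded: it is the
#: one measure without a reliable age trend).
RETAINED_METRICS = [m for m in ALL_METRICS if m != "k_core"]


def _to_graph(m: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    n = m.shape[0]
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(m, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        g.add_edge(i, j, weight=float(m[i, j]), length=1.0 / float(m[i, j]))
    return g


def degree_strength(m: np.ndarray) -> dict[str, np.ndarray | float]:
    """Per-node degree (nonzero-neighbor count) and strength (row sum)."""
    m = validate_matrix(m)
    degree = np.count_nonzero(m, axis=1).astype(float)
    strength = m.sum(axis=1)
    return {
        "degree": degree,
        "strength": strength,
        "avg_degree": float(degree.mean()),
        "max_degree": float(degree.max()),
        "avg_strength": float(strength.mean()),
        "max_strength": float(strength.max()),
    }


def _distance_matrix(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(m > 0, 1.0 / np.where(m > 0, m, 1.0), 0.0)
    return shortest_path(csr_array(lengths), method="D", directed=False)


def shortest_path_metrics(m: np.ndarray) -> dict[str, float | bool]:
    """Characteristic path length and global efficiency (lengths 1/w)."""
    m = validate_matrix(m)
    d = _distance_matrix(m)
    iu = np.triu_indices(m.shape[0], k=1)
    pair_d = d[iu]
    finite = np.isfinite(pair_d)
    disconnected = not bool(finite.all())
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(pair_d > 0, pair_d, np.inf), 0.0)
    efficiency = float(inv.mean())
    cpl = float(pair_d[finite].mean()) if finite.any() else float("nan")
    return {
        "char_path_length": cpl,
        "global_efficiency": efficiency,
        "disconnected": disconnected,
    }


def clustering_and_local_efficiency(m: np.ndarray) -> dict[str, np.ndarray]:
    """Per-node weighted clustering and local efficiency.

    Clustering is the geometric-mean triangle intensity; local efficiency
    is the global efficiency of each node's neighborhood subgraph.
    Nodes with degree < 2 score 0 on both, by convention.
    """
    m = validate_matrix(m)
    n = m.shape[0]
    g = _to_graph(m)
    cc = nx.clustering(g, weight="weight")
    clustering = np.array([cc[i] for i in range(n)])
    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(m[i])
        if nbrs.size < 2:
            continue
        sub = m[np.ix_(nbrs, nbrs)]
        local_eff[i] = shortest_path_metrics(sub)["global_efficiency"]
    return {"clustering": clustering, "local_efficiency": local_eff}


def rewire_preserving_degree(
    m: np.ndarray, rng: np.random.Generator, n_swaps_per_edge: int = 10
) -> np.ndarray:
    """Maslov-Sneppen double-edge swaps carrying weights.

    Preserves the degree sequence, the edge count (hence density) and the
    weight multiset.  Swaps creating self-loops or multi-edges are
    rejected.
    """
    m = validate_matrix(m)
    iu, ju = np.nonzero(np.triu(m, k=1))
    edges = [(int(a), int(b), float(m[a, b])) for a, b in zip(iu, ju)]
    ne = len(edges)
    if ne < 2:
        return m.copy()
    present = {(a, b) for a, b, _ in edges}

    def has(a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in present

    n_attempts = n_swaps_per_edge * ne
    for _ in range(n_attempts):
        e1, e2 = rng.choice(ne, size=2, replace=False)
        a, b, w1 = edges[e1]
        c, d, w2 = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if len({a, b, c, d}) < 4:
            continue
        if has(a, d) or has(c, b):
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add((min(a, d), max(a, d)))
        present.add((min(c, b), max(c, b)))
        edges[e1] = (min(a, d), max(a, d), w1)
        edges[e2] = (min(c, b), max(c, b), w2)
    out = np.zeros_like(m)
    for a, b, w in edges:
        out[a, b] = out[b, a] = w
    return out


def small_worldness(
    m: np.ndarray, n_null: int = 10, seed: int = 0
) -> float:
    """Sigma = (C/<C_null>) / (L/<L_null>) over rewired nulls."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    m = validate_matrix(m)
    c_obs = float(clustering_and_local_efficiency(m)["clustering"].mean())
    l_obs = shortest_path_metrics(m)["char_path_length"]
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        null = rewire_preserving_degree(m, rng)
        c_null.append(float(clustering_and_local_efficiency(null)["clustering"].mean()))
        l_null.append(shortest_path_metrics(null)["char_path_length"])
    c_bar, l_bar = float(np.mean(c_null)), float(np.mean(l_null))
    if c_bar == 0 or not np.isfinite(l_bar):
        raise ValueError("degenerate null ensemble (zero clustering or disconnected)")
    return float((c_obs / c_bar) / (l_obs / l_bar))


def modularity(
    m: np.ndarray, gamma: float = 0.6, seed: int = 0, restarts: int = 10
) -> tuple[float, np.ndarray]:
    """Best Louvain modularity Q at resolution gamma over seeded restarts."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    m = validate_matrix(m)
    if m.max() == 0:
        raise ValueError("cannot partition an empty graph")
    g = _to_graph(m)
    best_q, best_labels = -np.inf, None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=seed + r
        )
        q = nx.community.modularity(g, comms, weight="weight", resolution=gamma)
        if q > best_q:
            best_q = q
            labels = np.empty(m.shape[0], dtype=int)
            for k, comm in enumerate(comms):
                labels[list(comm)] = k
            best_labels = labels
    return float(best_q), best_labels


@dataclass
class GammaSelection:
    """Resolution sweep: per-gamma KS statistic of observed vs null Q."""

    gamma_grid: np.ndarray
    ks_statistics: np.ndarray
    selected_gamma: float
    observed_q: dict[float, list[float]] = field(default_factory=dict)
    null_q: dict[float, list[float]] = field(default_factory=dict)


def select_gamma(
    matrices: list[np.ndarray],
    gamma_grid: np.ndarray | None = None,
    n_null: int = 1,
    seed: int = 0,
    restarts: int = 3,
) -> GammaSelection:
    """Pick the resolution where modularity is most non-random.

    At each gamma, observed Q values across the sample are compared with
    Q values of degree- and density-preserving rewired nulls by a
    two-sample Kolmogorov-Smirnov statistic; the gamma with the largest
    KS statistic wins (ties broken toward the smallest gamma).
    """
    if gamma_grid is None:
        gamma_grid = np.round(np.arange(0.2, 2.0 + 1e-9, 0.2), 10)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if gamma_grid.size == 0:
        raise ValueError("gamma grid must be nonempty")
    rng = np.random.default_rng(seed)
    nulls = []
    for m in matrices:
        for _ in range(n_null):
            nulls.append(rewire_preserving_degree(m, rng))
    ks_stats = np.full(gamma_grid.size, np.nan)
    obs_all: dict[float, list[float]] = {}
    null_all: dict[float, list[float]] = {}
    for gi, gamma in enumerate(gamma_grid):
        try:
            obs = [
                modularity(m, gamma=gamma, seed=seed, restarts=restarts)[0]
                for m in matrices
            ]
            nul = [
                modularity(m, gamma=gamma, seed=seed, restarts=restarts)[0]
                for m in nulls
            ]
        except ValueError as err:
            logger.info("gamma %.2f skipped: %s", gamma, err)
            continue
        obs_all[float(gamma)] = obs
        null_all[float(gamma)] = nul
        ks_stats[gi] = ks_2samp(obs, nul).statistic
    if np.all(np.isnan(ks_stats)):
        raise ValueError("modularity failed at every gamma")
    best = int(np.nanargmax(ks_stats))  # nanargmax -> first (smallest gamma) tie
    return GammaSelection(
        gamma_grid=gamma_grid,
        ks_statistics=ks_stats,
        selected_gamma=float(gamma_grid[best]),
        observed_q=obs_all,
        null_q=null_all,
    )


def _core_quality(m: np.ndarray, core: np.ndarray, iu) -> float:
    """Cosine similarity between weights and the ideal core/periphery
    pattern (1 on pairs touching the core, 0 on periphery-periphery)."""
    delta = (core[iu[0]] | core[iu[1]]).astype(float)
    w = m[iu]
    denom = np.linalg.norm(w) * np.linalg.norm(delta)
    if denom == 0:
        return 0.0
    return float(w @ delta / denom)


def core_periphery(
    m: np.ndarray, seed: int = 0, restarts: int = 10
) -> tuple[float, np.ndarray]:
    """Borgatti-Everett-style core/periphery fit.

    Maximizes the correlation (cosine form) between the weight matrix and
    an ideal pattern with a dense core and an empty periphery, by greedy
    single-node flips from seeded random starts.  Returns q in [0, 1] and
    the boolean core vector.
    """
    m = validate_matrix(m)
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    strength = m.sum(axis=1)
    starts = [strength > np.median(strength), np.ones(n, dtype=bool)]
    while len(starts) < restarts:
        starts.append(rng.random(n) < rng.uniform(0.2, 0.8))
    best_q, best_core = -1.0, np.ones(n, dtype=bool)
    for core in starts:
        core = core.copy()
        if not core.any():
            core[int(np.argmax(strength))] = True
        q = _core_quality(m, core, iu)
        improved = True
        while improved:
            improved = False
            for v in range(n):
                core[v] = ~core[v]
                if not core.any():
                    core[v] = ~core[v]
                    continue
                q_new = _core_quality(m, core, iu)
                if q_new > q + 1e-12:
                    q = q_new
                    improved = True
                else:
                    core[v] = ~core[v]
        if q > best_q:
            best_q, best_core = q, core.copy()
    return float(best_q), best_core


def _peel(values_of: np.ndarray, m: np.ndarray, weighted: bool) -> np.ndarray:
    """Generalized degeneracy peeling; returns per-node core numbers.

    Repeatedly removes the minimum-degree (or minimum-strength) node;
    each node's core number is the running maximum of the removal values.
    The result is independent of tie-break order.
    """
    n = m.shape[0]
    vals = values_of.astype(float).copy()
    active = np.ones(n, dtype=bool)
    core_num = np.zeros(n)
    level = 0.0
    for _ in range(n):
        idx = np.flatnonzero(active)
        v = idx[np.argmin(vals[idx])]
        level = max(level, vals[v])
        core_num[v] = level
        active[v] = False
        nbrs = np.flatnonzero((m[v] > 0) & active)
        if weighted:
            vals[nbrs] -= m[v, nbrs]
        else:
            vals[nbrs] -= 1
    return core_num


def k_core_size(m: np.ndarray, level: float | None = None) -> tuple[float, int]:
    """(level, node count) of the k-core.

    With no level given, reports the highest k whose core is nonempty;
    otherwise the size of the core at the requested k.
    """
    m = validate_matrix(m)
    degree = np.count_nonzero(m, axis=1).astype(float)
    if level is None:
        core_num = _peel(degree, m, weighted=False)
        if m.max() == 0:
            return 0.0, 0
        top = core_num.max()
        return float(top), int(np.sum(core_num >= top))
    return float(level), _core_size_at(m, level, weighted=False)


def s_core_size(m: np.ndarray, level: float | None = None) -> tuple[float, int]:
    """(level, node count) of the s-core, by strength peeling."""
    m = validate_matrix(m)
    strength = m.sum(axis=1)
    if level is None:
        core_num = _peel(strength, m, weighted=True)
        if m.max() == 0:
            return 0.0, 0
        top = core_num.max()
        return float(top), int(np.sum(core_num >= top - 1e-12))
    return float(level), _core_size_at(m, level, weighted=True)


def _core_size_at(m: np.ndarray, level: float, weighted: bool) -> int:
    active = np.ones(m.shape[0], dtype=bool)
    while True:
        sub = m[np.ix_(active, active)]
        vals = sub.sum(axis=1) if weighted else np.count_nonzero(sub, axis=1)
        drop = vals < level
        if not drop.any() or not active.any():
            break
        idx = np.flatnonzero(active)
        active[idx[drop]] = False
    return int(active.sum())


def betweenness(m: np.ndarray) -> np.ndarray:
    """Per-node betweenness on 1/w lengths (unnormalized, endpoints
    excluded, equal-length path multiplicities split fractionally)."""
    m = validate_matrix(m)
    g = _to_graph(m)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(m.shape[0])])


def subgraph_centrality(m: np.ndarray, binarize: bool = True) -> np.ndarray:
    """SC_i = sum_j v_ij^2 exp(lambda_j): exponentially weighted closed
    walks.  Computed on the binarized thresholded network by default."""
    m = validate_matrix(m)
    a = (m > 0).astype(float) if binarize else m
    lam, vec = np.linalg.eigh(a)
    return (vec**2) @ np.exp(lam)


def compute_all_metrics(
    m: np.ndarray,
    gamma: float = 0.6,
    n_null: int = 10,
    seed: int = 0,
    restarts: int = 10,
    include_small_world: bool = True,
) -> dict[str, float]:
    """Scalar summary of the 12 organizational measures (plus degree and
    density) for one normalized network."""
    m = validate_matrix(m)
    ds = degree_strength(m)
    sp = shortest_path_metrics(m)
    cl = clustering_and_local_efficiency(m)
    q_mod, _ = modularity(m, gamma=gamma, seed=seed, restarts=restarts)
    q_cp, _ = core_periphery(m, seed=seed)
    _, k_sz = k_core_size(m)
    _, s_sz = s_core_size(m)
    out = {
        "density": compute_density(m),
        "avg_degree": ds["avg_degree"],
        "max_degree": ds["max_degree"],
        "avg_strength": ds["avg_strength"],
        "max_strength": ds["max_strength"],
        "global_efficiency": sp["global_efficiency"],
        "char_path_length": sp["char_path_length"],
        "modularity": q_mod,
        "core_periphery": q_cp,
        "k_core": float(k_sz),
        "s_core": float(s_sz),
        "clustering": float(cl["clustering"].mean()),
        "local_efficiency": float(cl["local_efficiency"].mean()),
        "betweenness": float(betweenness(m).mean()),
        "subgraph_centrality": float(subgraph_centrality(m).mean()),
    }
    if include_small_world:
        out["small_worldness"] = small_worldness(m, n_null=n_null, seed=seed)
    return out


def metrics_table(
    cohort,
    gamma: float = 0.6,
    n_null: int = 10,
    seed: int = 0,
    restarts: int = 10,
    include_small_world: bool = True,
) -> pd.DataFrame:
    """Tidy table: one row per subject, one column per metric."""
    rows = []
    for rec in cohort:
        row = {
            "subject_id": rec.subject_id,
            "age": rec.age,
            "age_bin": rec.age_bin,
            "sex": rec.sex,
            "dataset": rec.dataset,
        }
        row.update(
            compute_all_metrics(
                rec.matrix, gamma=gamma, n_null=n_null, seed=seed,
                restarts=restarts, include_small_world=include_small_world,
            )
        )
        rows.append(row)
    return pd.DataFrame(rows)


def nodal_table(cohort) -> pd.DataFrame:
    """Per-subject, per-node local measures (long format)."""
    rows = []
    for rec in cohort:
        m = validate_matrix(rec.matrix)
        ds = degree_strength(m)
        cl = clustering_and_local_efficiency(m)
        bc = betweenness(m)
        sc = subgraph_centrality(m)
        for node in range(m.shape[0]):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "age": rec.age,
                    "age_bin": rec.age_bin,
                    "node": node,
                    "degree": ds["degree"][node],
                    "strength": ds["strength"][node],
                    "clustering": cl["clustering"][node],
                    "local_efficiency": cl["local_efficiency"][node],
                    "betweenness": bc[node],
                    "subgraph_centrality": sc[node],
                }
            )
    return pd.DataFrame(rows)
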