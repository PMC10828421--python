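"""Greedy correlation-graph decorrelation of microbial features.

Highly correlated taxa/pathways carry redundant association signal.  Features
are connected in a graph when their pairwise Spearman correlation exceeds a
threshold (default |rho| > 0.995); the greedy pass repeatedly keeps the
highest-degree node (seeded random tie-break), removes it and its neighbours,
and recomputes degrees on the residual graph.  The kept set is simultaneously
an independent set and a dominating set of the graph: no two kept features are
adjacent, and every discarded feature is adjacent to at least one kept one.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .io_qc import AbundanceTable


def correlation_graph(
    a: AbundanceTable, threshold: float = 0.995, edge_stat: str = "abs_rho"
) -> np.ndarray:
    """Boolean adjacency matrix of the feature correlation graph.

    ``edge_stat``: "abs_rho" (|Spearman rho| > threshold, default), "rho"
    (signed), or "rho2" (rho squared).
    """
    v = a.values.to_numpy(dtype=float)
    if v.shape[1] == 1:
        return np.zeros((1, 1), dtype=bool)
    rho = stats.spearmanr(v, axis=0).statistic
    rho = np.atleast_2d(rho)
    if edge_stat == "abs_rho":
        statv = np.abs(rho)
    elif edge_stat == "rho":
        statv = rho
    elif edge_stat == "rho2":
        statv = rho**2
    else:
        raise ValueError(f"unknown edge_stat {edge_stat!r}")
    adj = statv > threshold
    np.fill_diagonal(adj, False)
    return adj | adj.T


def greedy_representatives(
    a: AbundanceTable,
    threshold: float = 0.995,
    seed: int = 0,
    edge_stat: str = "abs_rho",
) -> tuple[list, dict]:
    """Select independent representative features by the greedy max-degree rule.

    Returns (kept feature names, map discarded feature -> its representative).
    """
    if a.n_features < 1:
        raise ValueError("need at least one feature")
    if not 0 < threshold:
        raise ValueError("threshold must be positive")
    if threshold >= 1:
        warnings.warn("threshold >= 1 keeps all features (no possible edges)")
    adj = correlation_graph(a, threshold=threshold, edge_stat=edge_stat)
    return greedy_from_adjacency(adj, a.features, seed=seed)


def greedy_from_adjacency(adj: np.ndarray, names, seed: int = 0) -> tuple[list, dict]:
    """Greedy max-degree dominating/independent set on a boolean adjacency matrix."""
    adj = np.array(adj, dtype=bool)
    np.fill_diagonal(adj, False)
    rng = np.random.default_rng(seed)
    names = list(names)
    alive = np.ones(len(names), dtype=bool)
    kept: list = []
    rep_map: dict = {}
    while alive.any():
        degrees = (adj & alive).sum(axis=1)
        degrees[~alive] = -1
        max_deg = degrees.max()
        if max_deg == 0:
            kept.extend(names[i] for i in np.where(alive)[0])
            break
        ties = np.where(degrees == max_deg)[0]
        pick = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        kept.append(names[pick])
        neighbours = np.where(adj[pick] & alive)[0]
        for nb in neighbours:
            rep_map[names[nb]] = names[pick]
        alive[pick] = False
        alive[neighbours] = False
    return kept, rep_map
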