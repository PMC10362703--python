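"""Scoring of candidate graphs: decomposable Gaussian-linear BIC, the
trace-exponential acyclicity function h(A), a topological-sort DAG check,
and the combined reward

    reward = -[ BIC(G) + lambda1 * I(G not a DAG) + lambda2 * h(A) ].

The likelihood family is a Gaussian linear model per node with its own
residual variance: each node is regressed on its parents by least squares
with an intercept, and the node-local score is

    m * log(RSS / m) + k * log m,      k = |parents| + 1,

which is -2 * max log-likelihood plus the parameter-count penalty, with
the graph-independent additive constant m*(1 + log 2*pi) dropped.  The
total BIC is the sum of node-local terms, so scores are cached per
(node, parent-set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .data import Dataset

__all__ = [
    "RewardConfig", "RewardRecord", "node_local_bic", "bic_score",
    "acyclicity", "is_dag", "reward",
]

# RSS is clamped below at RSS_FLOOR_PER_ROW * m so deterministic
# parent-child relations give a finite (very favourable) score.
RSS_FLOOR_PER_ROW = 1e-8

ACYCLICITY_TOL = 1e-8


@dataclass(frozen=True)
class RewardConfig:
    """Penalty weights: ``lambda1`` multiplies the not-a-DAG indicator,
    ``lambda2`` multiplies h(A).  Defaults assume the trainer's BIC
    rescaling to [-1, 0]."""

    lambda1: float = 1.0
    lambda2: float = 10.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be nonnegative")


@dataclass(frozen=True)
class RewardRecord:
    """One scored graph: reward = -(bic + lambda1*[not is_dag] + lambda2*h)."""

    graph: np.ndarray
    bic: float
    h: float
    is_dag: bool
    reward: float


def _check_adjacency(graph: np.ndarray) -> np.ndarray:
    graph = np.asarray(graph)
    if graph.ndim != 2 or graph.shape[0] != graph.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.isin(graph, (0, 1)).all():
        raise ValueError("adjacency matrix must be binary")
    if np.any(np.diagonal(graph) != 0):
        raise ValueError("adjacency diagonal must be zero")
    return graph


def node_local_bic(data: Dataset, node: int, parents, cache: dict = None) -> float:
    """BIC contribution of one node given its parent set."""
    parents = tuple(sorted(set(int(p) for p in parents)))
    if node in parents:
        raise ValueError(f"node {node} cannot be its own parent")
    key = (node, parents)
    if cache is not None and key in cache:
        return cache[key]
    y = data.values[:, node]
    m = data.m
    design = np.column_stack([np.ones(m)] + [data.values[:, p] for p in parents])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design for node {node} with parents {parents}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = max(float(resid @ resid), RSS_FLOOR_PER_ROW * m)
    k = len(parents) + 1
    score = m * np.log(rss / m) + k * np.log(m)
    if cache is not None:
        cache[key] = score
    return score


def bic_score(graph: np.ndarray, data: Dataset, cache: dict = None) -> float:
    """Total BIC of a graph: sum of node-local scores (decomposable)."""
    graph = _check_adjacency(graph)
    if graph.shape[0] != data.d:
        raise ValueError("graph size does not match number of variables")
    total = 0.0
    for node in range(data.d):
        parents = np.flatnonzero(graph[:, node])
        total += node_local_bic(data, node, parents, cache)
    return total


def acyclicity(graph: np.ndarray) -> float:
    """h(A) = trace(e^A) - d; zero exactly on acyclic graphs."""
    graph = _check_adjacency(graph)
    d = graph.shape[0]
    h = float(np.trace(expm(graph.astype(float))) - d)
    return max(h, 0.0)


def is_dag(graph: np.ndarray) -> bool:
    """Kahn-style elimination: repeatedly remove in-degree-zero nodes."""
    graph = _check_adjacency(graph).astype(bool)
    alive = np.ones(graph.shape[0], dtype=bool)
    while alive.any():
        indeg = (graph[alive][:, alive]).sum(axis=0)
        roots = np.flatnonzero(alive)[indeg == 0]
        if roots.size == 0:
            return False
        alive[roots] = False
    return True


def reward(graph: np.ndarray, data: Dataset, cfg: RewardConfig = None,
           cache: dict = None) -> RewardRecord:
    """Score a graph and compose the penalized reward.

    For a DAG both penalty terms vanish and ``reward == -bic``.
    """
    cfg = cfg or RewardConfig()
    bic = bic_score(graph, data, cache)
    h = acyclicity(graph)
    dag = is_dag(graph)
    r = -(bic + cfg.lambda1 * (0.0 if dag else 1.0) + cfg.lambda2 * h)
    return RewardRecord(np.asarray(graph, dtype=np.int8), bic, h, dag, r)
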