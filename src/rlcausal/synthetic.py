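"""Ground-truth benchmarks: random DAGs, linear structural-equation data,
and structural Hamming distance, so the full pipeline is testable without
any external download.

Data are generated from a linear Gaussian SEM: in topological order each
node is the weighted sum of its parents plus independent Gaussian noise.
Edge weights default to +/- Uniform[0.5, 2] -- bounded away from zero so
generated structures are identifiable in practice -- and noise is unit
scale.  The implied covariance is (I - W)^-T D (I - W)^-1 with D the
diagonal of noise variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .scoring import is_dag

__all__ = ["GroundTruthSEM", "random_dag", "random_sem", "sample_linear_sem", "shd"]


@dataclass(frozen=True)
class GroundTruthSEM:
    dag: np.ndarray
    weights: np.ndarray
    noise_scale: np.ndarray

    def __post_init__(self):
        dag = np.asarray(self.dag, dtype=np.int8)
        weights = np.asarray(self.weights, dtype=float)
        noise = np.atleast_1d(np.asarray(self.noise_scale, dtype=float))
        if noise.size == 1:
            noise = np.full(dag.shape[0], noise[0])
        if np.any((weights != 0) & (dag == 0)):
            raise ValueError("weights must be zero where the DAG has no edge")
        if not is_dag(dag):
            raise ValueError("ground-truth graph must be acyclic")
        if np.any(noise <= 0):
            raise ValueError("noise scales must be positive")
        object.__setattr__(self, "dag", dag)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "noise_scale", noise)

    def implied_covariance(self) -> np.ndarray:
        d = self.dag.shape[0]
        inv = np.linalg.inv(np.eye(d) - self.weights)
        return inv.T @ np.diag(self.noise_scale ** 2) @ inv


def random_dag(d: int, edge_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Random DAG: Bernoulli strictly-upper-triangular matrix conjugated
    by a random node permutation (acyclic by construction)."""
    if not 2 <= d <= 50:
        raise ValueError("d must be in [2, 50]")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be a probability")
    upper = np.triu(rng.random((d, d)) < edge_prob, k=1).astype(np.int8)
    perm = rng.permutation(d)
    adj = np.zeros_like(upper)
    adj[np.ix_(perm, perm)] = upper
    return adj


def random_sem(d: int, edge_prob: float, rng: np.random.Generator,
               weight_range=(0.5, 2.0), noise_scale: float = 1.0) -> GroundTruthSEM:
    """Random DAG with edge weights of magnitude Uniform[weight_range]
    and random sign, and homoscedastic Gaussian noise."""
    dag = random_dag(d, edge_prob, rng)
    magnitude = rng.uniform(*weight_range, size=(d, d))
    sign = rng.choice([-1.0, 1.0], size=(d, d))
    return GroundTruthSEM(dag, dag * magnitude * sign, noise_scale)


def _topological_order(dag: np.ndarray) -> list:
    d = dag.shape[0]
    indeg = dag.sum(axis=0).astype(int)
    order, stack = [], [j for j in range(d) if indeg[j] == 0]
    while stack:
        j = stack.pop()
        order.append(j)
        for k in np.flatnonzero(dag[j]):
            indeg[k] -= 1
            if indeg[k] == 0:
                stack.append(int(k))
    if len(order) != d:
        raise ValueError("graph is cyclic")
    return order


def sample_linear_sem(sem: GroundTruthSEM, m: int, rng: np.random.Generator,
                      columns=None) -> Dataset:
    """Draw m rows from the linear Gaussian SEM."""
    if m < 2:
        raise ValueError("need m >= 2 rows")
    d = sem.dag.shape[0]
    values = np.zeros((m, d))
    for j in _topological_order(sem.dag):
        noise = rng.normal(0.0, sem.noise_scale[j], size=m)
        values[:, j] = values @ sem.weights[:, j] + noise
    return Dataset(values, columns)


def shd(truth: np.ndarray, estimate: np.ndarray) -> int:
    """Structural Hamming distance between two directed graphs.

    Counts edge insertions, deletions, and reversals needed to turn the
    estimate into the truth; a reversed edge costs 1, not 2.
    """
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    if truth.shape != estimate.shape or truth.ndim != 2:
        raise ValueError("graphs must be square matrices of the same size")
    d = truth.shape[0]
    total = 0
    for i in range(d):
        for j in range(i + 1, d):
            a = (int(truth[i, j]), int(truth[j, i]))
            b = (int(estimate[i, j]), int(estimate[j, i]))
            if a == b:
                continue
            if a in ((0, 1), (1, 0)) and b in ((0, 1), (1, 0)):
                total += 1          # pure reversal
            else:
                total += abs(a[0] - b[0]) + abs(a[1] - b[1])
    return total
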