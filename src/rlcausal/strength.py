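"""Inverse-information-entropy (IIE) causal strength.

Stage 2 of the pipeline: estimate each variable's differential entropy
with the order-statistics spacing estimator

    S_hat(X) = psi(n) - psi(1) + (1/(n-1)) * sum_i log|x_(i+1) - x_(i)|

(psi is the digamma function; natural logarithms, so entropies are in
nats), annotate every discovered edge i -> j with the strength

    T = 1 / |S_hat(X_j) - S_hat(X_i)|,

and prune edges whose strength falls below a threshold (default 0.5;
edges at exactly the threshold are kept).  T is symmetric in its two
arguments: it weights an edge but never orients it -- orientation comes
only from the graph search.

Repeated sample values give zero spacings, whose log is undefined.  The
default policy drops zero spacings from the sum and averages over the
remaining count; an ``epsilon`` policy floors spacings at 1e-12 instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .data import Dataset

__all__ = ["EntropyEstimate", "WeightedCausalGraph", "spacing_entropy",
           "iie_strength", "annotate_and_prune"]

STRENGTH_CAP = 1e12
_EQUAL_ENTROPY_TOL = 1e-12
_EPSILON_SPACING = 1e-12


@dataclass(frozen=True)
class EntropyEstimate:
    """Spacing-estimator differential entropy in nats."""

    value: float
    n: int
    zero_spacings: int


@dataclass(frozen=True)
class WeightedCausalGraph:
    """Directed edges annotated with IIE strengths.

    ``edges`` is a tuple of (source, target, strength) with variable
    names; always a subset of the stage-1 graph's edges.
    """

    variables: tuple
    edges: tuple

    def adjacency(self) -> np.ndarray:
        index = {v: i for i, v in enumerate(self.variables)}
        adj = np.zeros((len(self.variables),) * 2, dtype=np.int8)
        for src, dst, _ in self.edges:
            adj[index[src], index[dst]] = 1
        return adj


def spacing_entropy(column, tie_policy: str = "drop") -> EntropyEstimate:
    """Estimate differential entropy from adjacent order-statistic spacings."""
    x = np.sort(np.asarray(column, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample values")
    spacings = np.diff(x)
    n_zero = int(np.count_nonzero(spacings == 0))
    if n_zero == n - 1:
        raise ValueError("all values identical: entropy undefined")
    if tie_policy == "drop":
        logs = np.log(spacings[spacings > 0])
        mean_log = logs.sum() / logs.size
    elif tie_policy == "epsilon":
        mean_log = float(np.mean(np.log(np.maximum(spacings, _EPSILON_SPACING))))
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    value = float(digamma(n) - digamma(1) + mean_log)
    return EntropyEstimate(value, n, n_zero)


def iie_strength(col_a, col_b, tie_policy: str = "drop") -> float:
    """IIE strength 1 / |S_hat(b) - S_hat(a)|.

    Pass raw columns for the raw-data variant or normalized columns for
    the normalized variant.  When the two entropies coincide (absolute
    difference below 1e-12) the strength is capped at 1e12 rather than
    diverging.
    """
    s_a = spacing_entropy(col_a, tie_policy).value
    s_b = spacing_entropy(col_b, tie_policy).value
    diff = abs(s_b - s_a)
    if diff < _EQUAL_ENTROPY_TOL:
        return STRENGTH_CAP
    return min(1.0 / diff, STRENGTH_CAP)


def annotate_and_prune(graph: np.ndarray, data: Dataset, threshold: float = 0.5,
                       tie_policy: str = "drop") -> WeightedCausalGraph:
    """Annotate each edge of a stage-1 graph with its IIE strength and
    drop edges with strength strictly below ``threshold``.

    The strength at exactly the threshold is kept (the pruning rule
    removes only strictly weaker edges).  ``data`` should be the same
    (normalized) table the graph was discovered on.
    """
    graph = np.asarray(graph)
    if graph.shape != (data.d, data.d):
        raise ValueError("graph size does not match number of variables")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    entropies = [spacing_entropy(data.values[:, j], tie_policy).value
                 for j in range(data.d)]
    edges = []
    for i, j in np.argwhere(graph == 1):
        diff = abs(entropies[j] - entropies[i])
        strength = STRENGTH_CAP if diff < _EQUAL_ENTROPY_TOL else min(1.0 / diff,
                                                                      STRENGTH_CAP)
        if strength >= threshold:
            edges.append((data.columns[i], data.columns[j], float(strength)))
    return WeightedCausalGraph(tuple(data.columns), tuple(edges))
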