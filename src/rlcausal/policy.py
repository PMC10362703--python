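"""The graph-generation policy: embed variables, encode with stacked
self-attention, decode pairwise edge logits, and sample binary adjacency
matrices from independent Bernoulli edge distributions.

Each of the d variables is represented by n_s observation rows drawn
uniformly without replacement from the dataset (the same rows for every
variable, so identical columns map to identical embeddings), projected
linearly to ``d_model``.  No positional encoding is added: the variables
are an unordered set, and the encoder is permutation-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .nn import Critic, EncoderLayer, Linear, PairwiseDecoder

__all__ = ["EncoderConfig", "PolicyNetwork", "sample_graph", "bernoulli_log_prob"]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters for the policy network.

    ``n_layers=6`` and ``d_model=512`` are the full-size defaults; tests
    and small problems use a reduced network (e.g. 2 layers, width 16).
    ``d_ff=None`` means the conventional ``4 * d_model``.  ``n_s`` is the
    number of observation rows drawn to represent each variable.
    """

    n_layers: int = 6
    d_model: int = 512
    n_heads: int = 8
    d_ff: int = None
    n_s: int = 64

    def __post_init__(self):
        if min(self.n_layers, self.d_model, self.n_heads, self.n_s) < 1:
            raise ValueError("all encoder dimensions must be >= 1")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def ff_width(self) -> int:
        return 4 * self.d_model if self.d_ff is None else self.d_ff


class PolicyNetwork:
    """Embedding + attention encoder + pairwise Bernoulli-logit decoder.

    Parameters
    ----------
    cfg : EncoderConfig
    rng : numpy Generator used only for weight initialization.
    d_hidden : decoder hidden width d_h; defaults to ``d_model``.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 d_hidden: int = None):
        self.cfg = cfg
        self.embedding = Linear(cfg.n_s, cfg.d_model, rng)
        self.layers = [
            EncoderLayer(cfg.d_model, cfg.n_heads, cfg.ff_width, rng)
            for _ in range(cfg.n_layers)
        ]
        self.decoder = PairwiseDecoder(cfg.d_model, d_hidden or cfg.d_model, rng)

    # ---- forward ----------------------------------------------------

    def embed_variables(self, data: Dataset, rng: np.random.Generator,
                        rows: np.ndarray = None) -> np.ndarray:
        """Represent each variable by n_s sampled rows projected to d_model.

        The same rows are used for every variable, so cross-variable
        dependence survives the subsampling (and identical columns map
        to identical embeddings).  ``rows`` may be passed explicitly to
        reuse one subsample across calls.  Returns a (d, d_model)
        matrix.  Raises if ``n_s > m``.
        """
        n_s = self.cfg.n_s
        if n_s > data.m:
            raise ValueError(f"n_s={n_s} exceeds the {data.m} available rows")
        if rows is None:
            rows = rng.choice(data.m, size=n_s, replace=False)
        samples = data.values[rows]              # (n_s, d), same rows per variable
        return self.embedding.forward(samples.T)

    def encode(self, emb: np.ndarray) -> np.ndarray:
        """Run the stacked residual attention encoder; output (d, d_model)."""
        x = emb
        for layer in self.layers:
            x = layer.forward(x)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite encoder activations")
        return x

    def edge_logits(self, enc: np.ndarray) -> np.ndarray:
        """Pairwise logits g[i, j] = u^T tanh(W1 enc_i + W2 enc_j).

        The full (d, d) matrix is returned; the diagonal is computed but
        masked at sampling time (self-loops are never drawn).
        """
        return self.decoder.forward(enc)

    def forward(self, data: Dataset, rng: np.random.Generator,
                rows: np.ndarray = None):
        emb = self.embed_variables(data, rng, rows)
        enc = self.encode(emb)
        return enc, self.edge_logits(enc)

    # ---- backward ---------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for a loss with gradient
        ``dlogits`` with respect to the decoder output."""
        dx = self.decoder.backward(dlogits)
        for layer in reversed(self.layers):
            dx = layer.backward(dx)
        self.embedding.backward(dx)

    def params(self):
        out = self.embedding.params()
        for layer in self.layers:
            out += layer.params()
        return out + self.decoder.params()

    # ---- persistence ------------------------------------------------

    def save(self, path) -> None:
        np.savez(path, **{f"p{i}": p.value for i, p in enumerate(self.params())})

    def load(self, path) -> None:
        with np.load(path) as archive:
            for i, p in enumerate(self.params()):
                p.value[...] = archive[f"p{i}"]


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # log sigma(x) computed stably for large |x|
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))),
                    x - np.log1p(np.exp(-np.abs(x))))


def bernoulli_log_prob(adjacency: np.ndarray, logits: np.ndarray) -> float:
    """Total log-probability of a sampled adjacency matrix: the sum of
    edgewise Bernoulli log-masses over the off-diagonal entries."""
    d = logits.shape[0]
    off = ~np.eye(d, dtype=bool)
    log_p = _log_sigmoid(logits)
    log_q = _log_sigmoid(-logits)
    return float(np.sum(np.where(adjacency == 1, log_p, log_q)[off]))


def sample_graph(logits: np.ndarray, rng: np.random.Generator):
    """Draw one adjacency matrix, entrywise Bernoulli(sigma(logit)).

    The diagonal is forced to zero (no self-loops) and never consulted.
    Returns ``(adjacency, total_log_probability)``.
    """
    d = logits.shape[0]
    if not np.all(np.isfinite(logits[~np.eye(d, dtype=bool)])):
        raise ValueError("off-diagonal logits must be finite")
    p = 1.0 / (1.0 + np.exp(-logits))
    adjacency = (rng.random((d, d)) < p).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return adjacency, bernoulli_log_prob(adjacency, logits)
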