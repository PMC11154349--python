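"""Dynamic graph-structure learning from windowed signals and hidden state.

At each time step a short window of the reconstructed signal is fused with
the recurrent hidden state into per-channel node features, diffused over
the predefined distance graph, embedded through a saturating tanh, and
turned into a directed instantaneous adjacency by asymmetric similarity.
Averaging the last n instantaneous matrices slows the rate of change of
the inferred network; top-k row sparsification keeps it sparse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .eeg import PredefinedGraph, normalized_adjacency
from .nn import Tensor


@dataclass
class GraphLearnConfig:
    window_K: int = 10
    avg_steps_n: int = 4
    alpha: float = 3.0
    k_edges: int = 5
    feature_dim: int = 16

    def __post_init__(self):
        if self.window_K < 1:
            raise ValueError("window_K must be >= 1")
        if self.avg_steps_n < 1:
            raise ValueError("avg_steps_n must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k_edges < 1:
            raise ValueError("k_edges must be >= 1")


@dataclass
class DiffusionParams:
    """Two independent channel-mixing weights for source/destination branches."""

    theta1: Tensor      # [(K + d_h) x F']
    theta2: Tensor

    @classmethod
    def init(cls, in_dim: int, out_dim: int,
             rng: np.random.Generator | None = None) -> "DiffusionParams":
        rng = rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(in_dim)
        return cls(
            theta1=Tensor(rng.normal(0, s, size=(in_dim, out_dim)), requires_grad=True),
            theta2=Tensor(rng.normal(0, s, size=(in_dim, out_dim)), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.theta1, self.theta2]


# ------------------------------------------------------------ pipeline steps
def make_window(x_prime: np.ndarray, t: int, window_K: int) -> np.ndarray:
    """Window of the last K reconstructed steps ending at t, zero-padded left."""
    if window_K < 1:
        raise ValueError("window_K must be >= 1")
    x_prime = np.asarray(x_prime)
    n, m = x_prime.shape
    if not 0 <= t < n:
        raise ValueError("t out of range")
    lo = t - window_K + 1
    if lo >= 0:
        return x_prime[lo:t + 1].copy()
    out = np.zeros((window_K, m), dtype=x_prime.dtype)
    out[-(t + 1):] = x_prime[:t + 1]
    return out


def fuse_hidden(window: np.ndarray, hidden: np.ndarray) -> np.ndarray:
    """Per-channel concatenation of the window column and the hidden row."""
    window = np.asarray(window)
    hidden = np.asarray(hidden)
    if hidden.ndim != 2 or hidden.shape[0] != window.shape[1]:
        raise ValueError("hidden must have one row per channel")
    return np.concatenate([window.T, hidden], axis=1)


def fuse_hidden_t(window: Tensor, hidden: Tensor) -> Tensor:
    """Differentiable fuse; window [..., K, M], hidden [..., M, d_h]."""
    return nn.concat([window.swapaxes(-1, -2), hidden], axis=-1)


def predefined_diffusion(node_features, graph: PredefinedGraph,
                         params: DiffusionParams):
    """Message passing on the normalized predefined graph, two branches.

    Each branch computes A_hat @ I_t @ theta; accepts Tensor (training) or
    ndarray inputs.  Returns (DF1, DF2).
    """
    a_hat = normalized_adjacency(graph.weights)
    if isinstance(node_features, Tensor):
        mixed = Tensor(a_hat) @ node_features
        return mixed @ params.theta1, mixed @ params.theta2
    feats = np.asarray(node_features, dtype=np.float64)
    if feats.shape[-2] != a_hat.shape[0]:
        raise ValueError("node feature rows must match graph size")
    mixed = a_hat @ feats
    return mixed @ params.theta1.data, mixed @ params.theta2.data


def dynamic_embeddings(df1, df2, alpha: float):
    """Saturating embeddings tanh(alpha * DF); entries in (-1, 1)."""
    if isinstance(df1, Tensor):
        return (df1 * alpha).tanh(), (df2 * alpha).tanh()
    return np.tanh(alpha * np.asarray(df1)), np.tanh(alpha * np.asarray(df2))


def dynamic_adjacency(de1, de2, alpha: float):
    """Directed instantaneous adjacency from asymmetric node similarity.

    E = ReLU(tanh(alpha (DE1 DE2^T - DE2 DE1^T))); non-negative, zero
    diagonal, and never both (i,j) and (j,i) positive.
    """
    if isinstance(de1, Tensor):
        sim = de1 @ de2.T - de2 @ de1.T
        return (sim * alpha).tanh().relu()
    de1 = np.asarray(de1, dtype=np.float64)
    de2 = np.asarray(de2, dtype=np.float64)
    if de1.shape != de2.shape:
        raise ValueError("embedding shape mismatch")
    sim = de1 @ np.swapaxes(de2, -1, -2) - de2 @ np.swapaxes(de1, -1, -2)
    return np.maximum(np.tanh(alpha * sim), 0.0)


def temporal_average(buffer, n: int):
    """Entrywise mean of the last n instantaneous adjacencies.

    Early in a sequence fewer than n matrices exist; the mean is taken over
    what is available (no zero padding).
    """
    if len(buffer) == 0:
        raise ValueError("empty adjacency buffer")
    recent = list(buffer)[-n:]
    if isinstance(recent[0], Tensor):
        acc = recent[0]
        for e in recent[1:]:
            acc = acc + e
        return acc * (1.0 / len(recent))
    return np.mean(np.stack(recent), axis=0)


def topk_mask(m_t: np.ndarray, k_edges: int) -> np.ndarray:
    """Boolean mask keeping the k largest entries per row (ties: lower column)."""
    if k_edges < 1:
        raise ValueError("k_edges must be >= 1")
    m_t = np.asarray(m_t, dtype=np.float64)
    ncols = m_t.shape[-1]
    mask = np.zeros(m_t.shape, dtype=bool)
    if k_edges >= ncols:
        mask[...] = m_t != 0.0
        return mask
    # stable argsort on -values: among ties the lower column index wins
    order = np.argsort(-m_t, axis=-1, kind="stable")[..., :k_edges]
    np.put_along_axis(mask, order, True, axis=-1)
    mask &= m_t != 0.0   # rows with < k nonzeros keep only their nonzeros
    return mask


def sparsify_topk(m_t, k_edges: int):
    """Zero all but the k largest entries per row; Tensor or ndarray."""
    if isinstance(m_t, Tensor):
        mask = topk_mask(m_t.data, k_edges)
        return m_t * mask.astype(np.float64)
    return np.where(topk_mask(m_t, k_edges), m_t, 0.0)


# --------------------------------------------------- convenience full stage
def dynamic_graph_step(x_prime: np.ndarray, t: int, hidden: np.ndarray,
                       graph: PredefinedGraph, params: DiffusionParams,
                       cfg: GraphLearnConfig, buffer: list) -> np.ndarray:
    """One feed-forward pass of the dynamic-graph stage (inference path).

    Appends the instantaneous adjacency to ``buffer`` (trimmed to n) and
    returns the sparsified averaged adjacency M_t.
    """
    window = make_window(x_prime, t, cfg.window_K)
    feats = fuse_hidden(window, hidden)
    df1, df2 = predefined_diffusion(feats, graph, params)
    de1, de2 = dynamic_embeddings(df1, df2, cfg.alpha)
    e_t = dynamic_adjacency(de1, de2, cfg.alpha)
    buffer.append(e_t)
    del buffer[:-cfg.avg_steps_n]
    m_t = temporal_average(buffer, cfg.avg_steps_n)
    return sparsify_topk(m_t, cfg.k_edges)
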