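"""Graph-convolutional GRU over the learned dynamic adjacency, with
classification heads and the combined training objective.

The recurrent cell replaces the GRU's linear maps with graph convolutions
on the (sparsified, self-looped, symmetrically normalized) dynamic
adjacency; the final hidden state feeds a softmax head for seizure
detection (2 classes) or seizure-type classification (4 classes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .attention import AttentionParams, attention_reconstruct_t
from .eeg import PredefinedGraph, normalized_adjacency
from .graphs import (DiffusionParams, GraphLearnConfig, dynamic_adjacency,
                     dynamic_embeddings, fuse_hidden_t, sparsify_topk,
                     temporal_average, topk_mask)
from .nn import Tensor

DETECTION_CLASSES = 2
CLASSIFICATION_CLASSES = 4   # CF, GN, AB, CT


@dataclass
class ModelConfig:
    """Everything needed to rebuild the model deterministically."""

    n_channels: int = 19
    d_model: int = 64
    n_heads: int = 4
    window_K: int = 10
    avg_steps_n: int = 4
    alpha: float = 3.0
    k_edges: int = 5
    diffusion_dim: int = 16
    hidden_size: int = 16
    lambda_: float = 0.3
    block_size: int = 1024
    time_stride: int = 1
    temperature: float = 0.1
    seed: int = 0
    no_seizure_attention: bool = False   # ablation: X' = X, L_re = 0
    static_dist_graph: bool = False      # ablation: TGCN runs on Dist-Graph

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.k_edges > self.n_channels - 1:
            raise ValueError("k_edges must be <= M - 1")
        if self.time_stride < 1:
            raise ValueError("time_stride must be >= 1")


@dataclass
class TGCNParams:
    """Gate weights/biases of the graph-convolutional GRU cell."""

    w_u: Tensor
    b_u: Tensor
    w_r: Tensor
    b_r: Tensor
    w_c: Tensor
    b_c: Tensor

    @classmethod
    def init(cls, feat_dim: int, hidden: int,
             rng: np.random.Generator | None = None) -> "TGCNParams":
        rng = rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(feat_dim + hidden)
        def w():
            return Tensor(rng.normal(0, s, size=(feat_dim + hidden, hidden)),
                          requires_grad=True)
        def b():
            return Tensor(np.zeros(hidden), requires_grad=True)
        return cls(w_u=w(), b_u=b(), w_r=w(), b_r=b(), w_c=w(), b_c=b())

    def parameters(self) -> list[Tensor]:
        return [self.w_u, self.b_u, self.w_r, self.b_r, self.w_c, self.b_c]


@dataclass
class TGCNState:
    hidden: np.ndarray          # [M x d_h]
    update_gate: np.ndarray     # u_t in (0,1)
    reset_gate: np.ndarray      # r_t in (0,1)
    candidate: np.ndarray       # c_t in (-1,1)


@dataclass
class ModelOutput:
    logits: np.ndarray
    class_probabilities: np.ndarray


@dataclass
class LossTerms:
    cross_entropy: float
    l_re: float
    lambda_: float

    @property
    def total(self) -> float:
        return self.cross_entropy + self.lambda_ * self.l_re


# ----------------------------------------------------------- cell primitives
def _normalize_t(adj: Tensor) -> Tensor:
    """Differentiable D^-1/2 (A + I) D^-1/2 with row-sum degrees."""
    m = adj.shape[-1]
    a = adj + np.eye(m)
    d = a.sum(axis=-1)                                  # [..., M]
    dinv = (d + 1e-12) ** -0.5
    col = dinv.reshape(*dinv.shape, 1)                  # [..., M, 1]
    row = dinv.reshape(*dinv.shape[:-1], 1, m)          # [..., 1, M]
    return a * col * row


def tgcn_cell_t(feats: Tensor, hidden: Tensor, a_hat: Tensor,
                params: TGCNParams) -> tuple[Tensor, Tensor, Tensor]:
    """One differentiable cell step; returns (h_t, u_t, r_t, c_t is folded).

    ``feats`` [..., M, F], ``hidden`` [..., M, d_h], ``a_hat`` the already
    normalized adjacency [..., M, M].
    """
    f = feats.shape[-1]
    z = nn.concat([feats, hidden], axis=-1)
    az = a_hat @ z                       # graph conv shared by both gates
    u = nn.sigmoid(az @ params.w_u + params.b_u)
    r = nn.sigmoid(az @ params.w_r + params.b_r)
    # A [feats, r*h] = [A feats, A (r*h)]; A feats is the first block of az
    arh = a_hat @ (r * hidden)
    c = (az[..., :f] @ params.w_c[:f] + arh @ params.w_c[f:]
         + params.b_c).tanh()
    h = u * hidden + (1.0 - u) * c
    return h, u, r, c


def tgcn_cell(node_features: np.ndarray, hidden: np.ndarray,
              adjacency: np.ndarray, params: TGCNParams) -> TGCNState:
    """Inference-path cell step on a raw (unnormalized) adjacency."""
    node_features = np.asarray(node_features, dtype=np.float64)
    hidden = np.asarray(hidden, dtype=np.float64)
    adjacency = np.asarray(adjacency, dtype=np.float64)
    if adjacency.shape[0] != node_features.shape[0]:
        raise ValueError("adjacency and node features disagree on M")
    with nn.no_grad():
        a_hat = Tensor(normalized_adjacency(adjacency))
        h, u, r, c = tgcn_cell_t(Tensor(node_features), Tensor(hidden),
                                 a_hat, params)
    return TGCNState(hidden=h.data, update_gate=u.data,
                     reset_gate=r.data, candidate=c.data)


def cross_entropy_t(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy; stable log-softmax via a constant shift."""
    shift = logits.data.max(axis=-1, keepdims=True)
    z = logits - shift
    lse = (z.exp().sum(axis=-1, keepdims=True)).log()
    logp = z - lse
    labels = np.asarray(labels, dtype=int)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()


# ------------------------------------------------------------------- model
class DTGCN:
    """Dynamic temporal graph convolutional network.

    Encodes a clip by reconstructing it once with the seizure-attention
    module, then iterating the dynamic-graph stage and the TGCN cell over
    time; the last hidden state feeds the classification head.
    """

    def __init__(self, cfg: ModelConfig, dist_graph: PredefinedGraph):
        if dist_graph.n_nodes != cfg.n_channels:
            raise ValueError("dist graph size must match channel count")
        self.cfg = cfg
        self.dist_graph = dist_graph
        rng = np.random.default_rng(cfg.seed)
        self.attention = AttentionParams.init(
            cfg.n_channels, cfg.d_model, cfg.n_heads, rng)
        feat_in = cfg.window_K + cfg.hidden_size
        self.diffusion = DiffusionParams.init(feat_in, cfg.diffusion_dim, rng)
        self.tgcn = TGCNParams.init(feat_in, cfg.hidden_size, rng)
        flat = cfg.n_channels * cfg.hidden_size
        s = 1.0 / np.sqrt(flat)
        self.w_det = Tensor(rng.normal(0, s, size=(flat, DETECTION_CLASSES)),
                            requires_grad=True)
        self.b_det = Tensor(np.zeros(DETECTION_CLASSES), requires_grad=True)
        self.w_cls = Tensor(rng.normal(0, s, size=(flat, CLASSIFICATION_CLASSES)),
                            requires_grad=True)
        self.b_cls = Tensor(np.zeros(CLASSIFICATION_CLASSES), requires_grad=True)
        self.tau = 0.0
        self._a_pre = normalized_adjacency(dist_graph.weights)
        self.stats = {"max_row_nnz": 0}

    # ------------------------------------------------------------- plumbing
    def parameters(self) -> list[Tensor]:
        ps = (self.attention.parameters() + self.diffusion.parameters()
              + self.tgcn.parameters()
              + [self.w_det, self.b_det, self.w_cls, self.b_cls])
        return ps

    def graph_config(self) -> GraphLearnConfig:
        c = self.cfg
        return GraphLearnConfig(window_K=c.window_K, avg_steps_n=c.avg_steps_n,
                                alpha=c.alpha, k_edges=c.k_edges,
                                feature_dim=c.diffusion_dim)

    # -------------------------------------------------------------- forward
    def reconstruct(self, x: Tensor) -> Tensor:
        if self.cfg.no_seizure_attention:
            return x
        return attention_reconstruct_t(x, self.attention, self.cfg.block_size)

    def encode(self, x: Tensor, collect_adjacency: bool = False):
        """Run the full recurrence on ``x`` [B, N, M] (or [N, M]).

        Returns (h_N, x_prime) and, when requested, the time-mean of the
        sparsified dynamic adjacency as a NumPy array.
        """
        single = x.ndim == 2
        if single:
            x = x.reshape(1, *x.shape)
        b, n, m = x.shape
        cfg = self.cfg
        x_prime = self.reconstruct(x)
        h = Tensor(np.zeros((b, m, cfg.hidden_size)))
        a_pre = Tensor(self._a_pre)
        static_a_hat = Tensor(normalized_adjacency(
            sparsify_topk(self.dist_graph.weights, cfg.k_edges)))
        buffer: list[Tensor] = []
        adj_sum = np.zeros((b, m, m))
        n_vis = 0
        k = cfg.window_K
        for t in range(cfg.time_stride - 1, n, cfg.time_stride):
            lo = t - k + 1
            if lo >= 0:
                window = x_prime[:, lo:t + 1, :]
            else:
                pad = Tensor(np.zeros((b, -lo, m)))
                window = nn.concat([pad, x_prime[:, :t + 1, :]], axis=1)
            feats = fuse_hidden_t(window, h)            # [B, M, K+d_h]
            if cfg.static_dist_graph:
                a_hat = static_a_hat
            else:
                mixed = a_pre @ feats
                de1, de2 = dynamic_embeddings(mixed @ self.diffusion.theta1,
                                              mixed @ self.diffusion.theta2,
                                              cfg.alpha)
                e_t = dynamic_adjacency(de1, de2, cfg.alpha)
                buffer.append(e_t)
                del buffer[:-cfg.avg_steps_n]
                m_t = temporal_average(buffer, cfg.avg_steps_n)
                mask = topk_mask(m_t.data, cfg.k_edges)
                self.stats["max_row_nnz"] = max(
                    self.stats["max_row_nnz"], int(mask.sum(axis=-1).max()))
                sparse = m_t * mask.astype(np.float64)
                a_hat = _normalize_t(sparse)
                if collect_adjacency:
                    adj_sum += sparse.data
                    n_vis += 1
            h, _, _, _ = tgcn_cell_t(feats, h, a_hat, self.tgcn)
        if single:
            h = h.reshape(*h.shape[1:])
        if collect_adjacency:
            mean_adj = adj_sum / max(n_vis, 1)
            return h, x_prime, (mean_adj[0] if single else mean_adj)
        return h, x_prime

    def logits(self, h: Tensor, head: str = "detection") -> Tensor:
        flat = h.reshape(h.shape[0], -1) if h.ndim == 3 else h.reshape(1, -1)
        if head == "detection":
            return flat @ self.w_det + self.b_det
        if head == "classification":
            return flat @ self.w_cls + self.b_cls
        raise ValueError(f"unknown head {head!r}")


# ------------------------------------------------------------- spec surface
def encode_clip(clip, model: DTGCN) -> np.ndarray:
    """Final hidden state h_N [M x d_h] for one clip (inference)."""
    if clip.signal.shape[0] < 1:
        raise ValueError("clip must contain at least one time step")
    with nn.no_grad():
        h, _ = model.encode(Tensor(clip.signal))
    return h.data


def classify(h_n: np.ndarray, model: DTGCN, head: str = "detection") -> ModelOutput:
    """Flatten the final hidden state, apply the head, softmax the logits."""
    with nn.no_grad():
        logit = model.logits(Tensor(np.asarray(h_n, dtype=np.float64)), head)
    z = logit.data - logit.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    return ModelOutput(logits=np.squeeze(logit.data, 0),
                       class_probabilities=np.squeeze(probs, 0))


def total_loss(output: ModelOutput, true_label: int, l_re: float,
               lambda_: float) -> LossTerms:
    """Cross-entropy on the true class plus the weighted reconstruction loss."""
    if l_re < 0 or lambda_ < 0:
        raise ValueError("l_re and lambda must be non-negative")
    p = output.class_probabilities[true_label]
    if p < 1e-12:
        import warnings
        warnings.warn("true-class probability underflow; clamping at 1e-12")
        p = 1e-12
    return LossTerms(cross_entropy=float(-np.log(p)), l_re=float(l_re),
                     lambda_=lambda_)


# ------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: DTGCN) -> None:
    """Parameters + config together; loading restores bit-identical forwards."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["dist_weights"] = model.dist_graph.weights
    arrays["tau"] = np.array(model.tau)
    meta = dict(asdict(model.cfg),
                kernel_sigma=model.dist_graph.kernel_sigma,
                threshold_kappa=model.dist_graph.threshold_kappa)
    np.savez(path, config=json.dumps(meta), **arrays)


def load_checkpoint(path) -> DTGCN:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["config"]))
        sigma = meta.pop("kernel_sigma")
        kappa = meta.pop("threshold_kappa")
        graph = PredefinedGraph(weights=z["dist_weights"], kernel_sigma=sigma,
                                threshold_kappa=kappa)
        model = DTGCN(ModelConfig(**meta), graph)
        for i, p in enumerate(model.parameters()):
            p.data = z[f"p{i}"].copy()
        model.tau = float(z["tau"])
    return model
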