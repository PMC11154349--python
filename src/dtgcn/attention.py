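"""Self-attention signal reconstruction and label-constrained anomaly scoring.

A clip is reconstructed by multi-head scaled dot-product attention over its
time steps; per-step reconstruction errors act as anomaly scores.  A
threshold tau, searched over 50 uniform candidates, converts errors into
predicted seizure steps, and the reconstruction loss is augmented with the
mismatch between predicted and labelled seizure-step counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

N_THRESHOLD_CANDIDATES = 50


# --------------------------------------------------------------------- types
@dataclass
class AttentionParams:
    """Learnable projections for multi-head self-attention reconstruction.

    Queries/keys/values are three separate projections of the input
    (channels -> d_model); an output projection maps the attended values
    back to channel space.
    """

    w_q: Tensor
    w_k: Tensor
    w_v: Tensor
    w_out: Tensor
    n_heads: int

    @property
    def d_model(self) -> int:
        return self.w_q.shape[1]

    @classmethod
    def init(cls, n_channels: int, d_model: int = 64, n_heads: int = 4,
             rng: np.random.Generator | None = None,
             qk_scale: float = 0.3) -> "AttentionParams":
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        rng = rng or np.random.default_rng(0)
        def proj(scale):
            return Tensor(rng.normal(0.0, scale, size=(n_channels, d_model)),
                          requires_grad=True)
        # value/output initialized so w_v @ w_out ~ identity and w_k = w_q:
        # attention starts self-peaked (each step attends to itself and
        # similar steps), so the initial reconstruction is a near-copy of
        # the input and downstream modules see signal from epoch 0.
        eye = np.zeros((n_channels, d_model))
        k = min(n_channels, d_model)
        eye[:k, :k] = np.eye(k)
        w_v = Tensor(eye + rng.normal(0, 0.02, size=(n_channels, d_model)),
                     requires_grad=True)
        w_out = Tensor(eye.T.copy() + rng.normal(0, 0.02, size=(d_model, n_channels)),
                       requires_grad=True)
        w_q = proj(qk_scale / np.sqrt(n_channels))
        w_k = Tensor(w_q.data + rng.normal(0, 0.01, size=w_q.shape),
                     requires_grad=True)
        return cls(w_q=w_q, w_k=w_k, w_v=w_v, w_out=w_out, n_heads=n_heads)

    def parameters(self) -> list[Tensor]:
        return [self.w_q, self.w_k, self.w_v, self.w_out]


@dataclass
class AttentionState:
    """Reconstruction and diagnostics for one clip."""

    reconstruction: np.ndarray      # [N x M]
    scores: np.ndarray              # [heads x N x N], row-stochastic per block
    step_errors: np.ndarray         # [N]


@dataclass
class ThresholdResult:
    tau: float
    candidates: np.ndarray          # 50 values
    criterion_values: np.ndarray    # 50 values


@dataclass
class SeizureStepSets:
    true_steps: set
    predicted_steps: set


# ---------------------------------------------------------- core computation
def attention_reconstruct_t(x: Tensor, params: AttentionParams,
                            block_size: int = 1024) -> Tensor:
    """Differentiable reconstruction; ``x`` is [..., N, M].

    Attention is computed within non-overlapping time blocks of
    ``block_size`` steps to bound the O(N^2) score matrices on long clips.
    """
    n = x.shape[-2]
    scale = 1.0 / np.sqrt(params.d_model)
    h = params.n_heads
    dh = params.d_model // h
    outs = []
    for start in range(0, n, block_size):
        xb = x[..., start:min(start + block_size, n), :]
        nb = xb.shape[-2]
        q = xb @ params.w_q   # [..., nb, d_model]
        k = xb @ params.w_k
        v = xb @ params.w_v
        # split heads: [..., nb, h, dh] -> [..., h, nb, dh]
        def heads(t: Tensor) -> Tensor:
            return t.reshape(*t.shape[:-1], h, dh).swapaxes(-2, -3)
        qh, kh, vh = heads(q), heads(k), heads(v)
        s = nn.softmax((qh @ kh.T) * scale, axis=-1)   # [..., h, nb, nb]
        av = s @ vh                                     # [..., h, nb, dh]
        merged = av.swapaxes(-2, -3).reshape(*xb.shape[:-1], params.d_model)
        outs.append(merged @ params.w_out)
    return nn.concat(outs, axis=-2)


def attention_scores(x: np.ndarray, params: AttentionParams,
                     block_size: int = 1024) -> np.ndarray:
    """Per-head attention scores [heads x N x N] (block-diagonal layout)."""
    n, _ = x.shape
    scale = 1.0 / np.sqrt(params.d_model)
    h = params.n_heads
    dh = params.d_model // h
    out = np.zeros((h, n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        xb = x[start:stop]
        q = xb @ params.w_q.data
        k = xb @ params.w_k.data
        for hd in range(h):
            qh = q[:, hd * dh:(hd + 1) * dh]
            kh = k[:, hd * dh:(hd + 1) * dh]
            logits = qh @ kh.T * scale
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out[hd, start:stop, start:stop] = e / e.sum(axis=1, keepdims=True)
    return out


def attention_reconstruct(x: np.ndarray, params: AttentionParams,
                          block_size: int = 1024) -> AttentionState:
    """Reconstruct one clip and compute per-step errors (inference path)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("x must be [N x M]")
    if x.shape[1] != params.w_q.shape[0]:
        raise ValueError("channel count does not match attention parameters")
    with nn.no_grad():
        recon = attention_reconstruct_t(Tensor(x), params, block_size).data
    return AttentionState(
        reconstruction=recon,
        scores=attention_scores(x, params, block_size),
        step_errors=reconstruction_errors(x, recon),
    )


def reconstruction_errors(x: np.ndarray, x_prime: np.ndarray) -> np.ndarray:
    """Euclidean norm of the per-time-step residual."""
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ValueError("shape mismatch between signal and reconstruction")
    return np.linalg.norm(x - x_prime, axis=-1)


# ----------------------------------------------------------- threshold logic
def _step_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def search_threshold(train_errors: np.ndarray, val_errors: np.ndarray,
                     val_fine_labels: np.ndarray) -> ThresholdResult:
    """Pick tau among 50 uniform candidates over the training-error range.

    The criterion is step-level F1 of (val_errors > tau) against the
    fine-grained labels; with no positive validation step it falls back to
    specificity.  Ties resolve to the smallest candidate.
    """
    train_errors = np.asarray(train_errors, dtype=np.float64)
    val_errors = np.asarray(val_errors, dtype=np.float64)
    val_fine_labels = np.asarray(val_fine_labels).astype(bool)
    if train_errors.size == 0 or val_errors.size == 0:
        raise ValueError("empty error vectors")
    if val_errors.shape != val_fine_labels.shape:
        raise ValueError("validation errors and labels misaligned")
    candidates = np.linspace(train_errors.min(), train_errors.max(),
                             N_THRESHOLD_CANDIDATES)
    has_pos = bool(val_fine_labels.any())
    crit = np.empty(N_THRESHOLD_CANDIDATES)
    for i, tau in enumerate(candidates):
        pred = val_errors > tau
        if has_pos:
            crit[i] = _step_f1(pred, val_fine_labels)
        else:
            neg = ~val_fine_labels
            crit[i] = np.sum(~pred & neg) / np.sum(neg)
    best = int(np.argmax(crit))  # argmax returns the first (smallest) maximizer
    return ThresholdResult(tau=float(candidates[best]), candidates=candidates,
                           criterion_values=crit)


def true_and_predicted_steps(fine_labels: np.ndarray, step_errors: np.ndarray,
                             tau: float) -> SeizureStepSets:
    """T1 = labelled seizure steps; T2 = steps with error strictly above tau."""
    fine_labels = np.asarray(fine_labels)
    step_errors = np.asarray(step_errors)
    if fine_labels.shape != step_errors.shape:
        raise ValueError("fine_labels and step_errors misaligned")
    return SeizureStepSets(
        true_steps=set(np.flatnonzero(fine_labels == 1).tolist()),
        predicted_steps=set(np.flatnonzero(step_errors > tau).tolist()),
    )


def constrained_reconstruction_loss(x: np.ndarray, x_prime: np.ndarray,
                                    step_sets: SeizureStepSets,
                                    n_steps: int) -> float:
    """Frobenius reconstruction error plus the normalized count mismatch."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    frob = float(np.linalg.norm(x - x_prime))
    count_term = abs(len(step_sets.true_steps) - len(step_sets.predicted_steps)) / n_steps
    return frob + count_term


def soft_anomaly_count(step_errors, tau: float, temperature: float = 0.1):
    """Differentiable surrogate for card(T2): sum of logistic step functions.

    Accepts a Tensor (training path) or an ndarray; converges to the hard
    count as temperature -> 0 whenever no error sits exactly at tau.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(step_errors, Tensor):
        return nn.sigmoid((step_errors - tau) * (1.0 / temperature)).sum(axis=-1)
    from scipy.special import expit
    z = (np.asarray(step_errors, dtype=np.float64) - tau) / temperature
    return float(np.sum(expit(z)))


def constrained_loss_t(x: Tensor, x_prime: Tensor, fine_labels: np.ndarray,
                       tau: float, temperature: float = 0.1) -> Tensor:
    """Differentiable training-time version of the constrained loss.

    ``x``/``x_prime`` are [..., N, M]; fine_labels [..., N].  Returns the
    mean loss over leading batch dimensions.
    """
    n = x.shape[-2]
    resid = x - x_prime
    frob = ((resid * resid).sum(axis=(-1, -2)) + 1e-12) ** 0.5
    err = ((resid * resid).sum(axis=-1) + 1e-12) ** 0.5     # [..., N]
    soft = soft_anomaly_count(err, tau, temperature)        # [...]
    t1 = np.asarray(fine_labels).sum(axis=-1)
    loss = frob + (soft - t1).abs() * (1.0 / n)
    return loss.mean()
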