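"""Training loop, metrics, ablations, sweeps and connectivity analysis."""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from . import nn
from .attention import (constrained_loss_t, reconstruction_errors,
                        search_threshold, ThresholdResult)
from .eeg import EEGClip, PredefinedGraph, SEIZURE_CLASSES
from .model import (CLASSIFICATION_CLASSES, DTGCN, ModelConfig,
                    cross_entropy_t)
from .nn import Adam, Tensor

logger = logging.getLogger(__name__)

CLASS_ORDER = ("CF", "GN", "AB", "CT")


# --------------------------------------------------------------------- types
@dataclass
class TrainConfig:
    learning_rate: float = 5e-5
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 16
    seed: int = 0
    task: str = "detection"              # or "classification"
    multitask: bool = False              # shared encoder, both heads
    no_seizure_attention: bool = False
    static_dist_graph: bool = False
    threshold_sample_clips: int = 16     # clips used per tau re-search
    grad_clip: float = 10.0              # global grad-norm bound (0 = off)

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.task not in ("detection", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class EvalReport:
    auroc: float | None
    weighted_f1: float
    confusion: np.ndarray
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    classes: tuple
    threshold: ThresholdResult | None = None


@dataclass
class ConnectivityReport:
    class_means: dict
    differences: dict        # class -> (mean_class - mean_none)
    frobenius: dict          # class -> ||difference||_F


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


# ------------------------------------------------------------------- metrics
def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def weighted_f1(pred_classes: np.ndarray, true_classes: np.ndarray) -> float:
    """Support-weighted mean of per-class F1 scores."""
    pred_classes = np.asarray(pred_classes)
    true_classes = np.asarray(true_classes)
    if true_classes.size == 0:
        raise ValueError("empty inputs")
    return float(f1_score(true_classes, pred_classes, average="weighted",
                          zero_division=0))


def confusion_normalized(pred: np.ndarray, true: np.ndarray,
                         classes) -> np.ndarray:
    """Row-normalized confusion: entry (i,j) = P(pred=j | true=i)."""
    classes = list(classes)
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((k, k))
    for t, p in zip(true, pred):
        mat[index[t], index[p]] += 1
    sums = mat.sum(axis=1, keepdims=True)
    nonempty = sums[:, 0] > 0
    mat[nonempty] /= sums[nonempty]
    return mat


# ------------------------------------------------------------- data plumbing
def standardize_clip(signal: np.ndarray) -> np.ndarray:
    """Per-channel z-scoring within a clip."""
    mu = signal.mean(axis=0, keepdims=True)
    sd = signal.std(axis=0, keepdims=True)
    return (signal - mu) / np.maximum(sd, 1e-8)


def clips_to_arrays(clips: list[EEGClip], task: str):
    """Stack clips into (X, labels, fine).  For classification only seizure
    clips are kept and labels index CLASS_ORDER."""
    if task == "classification":
        clips = [c for c in clips if c.coarse_label == 1]
        labels = np.array([CLASS_ORDER.index(c.seizure_class) for c in clips])
    else:
        labels = np.array([c.coarse_label for c in clips])
    x = np.stack([standardize_clip(c.signal) for c in clips])
    fine = np.stack([c.fine_labels for c in clips])
    return x, labels, fine


# ------------------------------------------------------------ early stopping
class EarlyStopper:
    """Stop when validation loss has not improved for `patience` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0
        self.best_epoch = -1

    def update(self, loss: float, epoch: int) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


# ----------------------------------------------------------------- training
class Trainer:
    def __init__(self, model: DTGCN, cfg: TrainConfig):
        self.model = model
        self.cfg = cfg
        model.cfg.no_seizure_attention = cfg.no_seizure_attention
        model.cfg.static_dist_graph = cfg.static_dist_graph
        self.opt = Adam(model.parameters(), lr=cfg.learning_rate)

    # ---- helpers
    def _recon_errors(self, x: np.ndarray) -> np.ndarray:
        """Per-step reconstruction errors [n_clips, N] (inference path)."""
        with nn.no_grad():
            recon = self.model.reconstruct(Tensor(x)).data
        return reconstruction_errors(x, recon)

    def refresh_threshold(self, x_train, x_val, fine_val) -> ThresholdResult:
        k = self.cfg.threshold_sample_clips
        tr = self._recon_errors(x_train[:k]).ravel()
        va = self._recon_errors(x_val[:k])
        res = search_threshold(tr, va.ravel(), fine_val[:k].ravel())
        self.model.tau = res.tau
        return res

    def _batch_loss(self, xb: np.ndarray, yb: np.ndarray,
                    fineb: np.ndarray, yb2: np.ndarray | None = None) -> Tensor:
        model = self.model
        x = Tensor(xb)
        h, x_prime = model.encode(x)
        loss = cross_entropy_t(
            model.logits(h, "classification" if self.cfg.task == "classification"
                         else "detection"), yb)
        if self.cfg.multitask and yb2 is not None:
            loss = loss + cross_entropy_t(model.logits(h, "classification"), yb2)
        if not self.cfg.no_seizure_attention and model.cfg.lambda_ > 0:
            l_re = constrained_loss_t(x, x_prime, fineb, model.tau,
                                      model.cfg.temperature)
            loss = loss + l_re * model.cfg.lambda_
        return loss

    def _dataset_loss(self, x, y, fine) -> float:
        total, count = 0.0, 0
        bs = self.cfg.batch_size
        with nn.no_grad():
            for i in range(0, len(x), bs):
                l = self._batch_loss(x[i:i + bs], y[i:i + bs], fine[i:i + bs])
                total += float(l.data) * len(x[i:i + bs])
                count += len(x[i:i + bs])
        return total / max(count, 1)

    def predict_proba(self, x: np.ndarray, head: str = "detection") -> np.ndarray:
        out = []
        bs = self.cfg.batch_size
        with nn.no_grad():
            for i in range(0, len(x), bs):
                h, _ = self.model.encode(Tensor(x[i:i + bs]))
                logits = self.model.logits(h, head).data
                z = logits - logits.max(axis=-1, keepdims=True)
                e = np.exp(z)
                out.append(e / e.sum(axis=-1, keepdims=True))
        return np.concatenate(out)

    # ---- main loop
    def train(self, train_clips: list[EEGClip],
              val_clips: list[EEGClip]) -> TrainHistory:
        cfg = self.cfg
        if not train_clips or not val_clips:
            raise ValueError("train and validation sets must be nonempty")
        x_tr, y_tr, fine_tr = clips_to_arrays(train_clips, cfg.task)
        x_va, y_va, fine_va = clips_to_arrays(val_clips, cfg.task)
        rng = np.random.default_rng(cfg.seed)
        stopper = EarlyStopper(cfg.patience)
        history = TrainHistory()
        best_params = None

        if not cfg.no_seizure_attention:
            self.refresh_threshold(x_tr, x_va, fine_va)
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(x_tr))
            epoch_loss, seen = 0.0, 0
            for i in range(0, len(order), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                self.opt.zero_grad()
                loss = self._batch_loss(x_tr[idx], y_tr[idx], fine_tr[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}")
                loss.backward()
                if cfg.grad_clip > 0:
                    self.opt.clip_grad_norm(cfg.grad_clip)
                self.opt.step()
                epoch_loss += float(loss.data) * len(idx)
                seen += len(idx)
            val_loss = self._dataset_loss(x_va, y_va, fine_va)
            thr = None
            if not cfg.no_seizure_attention:
                thr = self.refresh_threshold(x_tr, x_va, fine_va)
            entry = {"epoch": epoch, "train_loss": epoch_loss / seen,
                     "val_loss": val_loss, "tau": self.model.tau}
            try:
                if cfg.task == "detection":
                    proba = self.predict_proba(x_va)[:, 1]
                    entry["val_auroc"] = auroc(proba, y_va)
                else:
                    proba = self.predict_proba(x_va, "classification")
                    entry["val_weighted_f1"] = weighted_f1(
                        proba.argmax(axis=1), y_va)
            except ValueError:
                pass  # single-class validation batch: metric undefined
            history.epochs.append(entry)
            logger.info("epoch %d: train %.4f val %.4f", epoch,
                        entry["train_loss"], val_loss)
            if val_loss < stopper.best:
                best_params = [p.data.copy() for p in self.model.parameters()]
            if stopper.update(val_loss, epoch):
                history.stopped_early = True
                break
        history.best_epoch = stopper.best_epoch
        if best_params is not None:
            for p, b in zip(self.model.parameters(), best_params):
                p.data = b
        return history


# --------------------------------------------------------------- evaluation
def evaluate(trainer: Trainer, clips: list[EEGClip],
             task: str | None = None) -> EvalReport:
    task = task or trainer.cfg.task
    x, y, _ = clips_to_arrays(clips, task)
    if task == "detection":
        proba = trainer.predict_proba(x, "detection")
        pred = proba.argmax(axis=1)
        classes = (0, 1)
        score = proba[:, 1]
        auc = auroc(score, y) if len(np.unique(y)) == 2 else None
    else:
        proba = trainer.predict_proba(x, "classification")
        pred = proba.argmax(axis=1)
        classes = tuple(range(CLASSIFICATION_CLASSES))
        auc = None
    labels = list(classes)
    return EvalReport(
        auroc=auc,
        weighted_f1=weighted_f1(pred, y),
        confusion=confusion_normalized(pred, y, labels),
        per_class_precision=precision_score(y, pred, labels=labels,
                                            average=None, zero_division=0),
        per_class_recall=recall_score(y, pred, labels=labels,
                                      average=None, zero_division=0),
        classes=classes,
    )


def connectivity_analysis(model: DTGCN, clips_by_class: dict,
                          batch_size: int = 8) -> ConnectivityReport:
    """Mean sparsified dynamic adjacency per class and differences vs none."""
    means = {}
    for cls, clips in clips_by_class.items():
        if not clips:
            logger.warning("connectivity: empty group %r skipped", cls)
            continue
        x = np.stack([standardize_clip(c.signal) for c in clips])
        acc = np.zeros((model.cfg.n_channels, model.cfg.n_channels))
        with nn.no_grad():
            for i in range(0, len(x), batch_size):
                _, _, adj = model.encode(Tensor(x[i:i + batch_size]),
                                         collect_adjacency=True)
                acc += adj.sum(axis=0)
        means[cls] = acc / len(x)
    diffs, frob = {}, {}
    if "none" in means:
        for cls, mat in means.items():
            if cls == "none":
                continue
            diffs[cls] = mat - means["none"]
            frob[cls] = float(np.linalg.norm(diffs[cls]))
    return ConnectivityReport(class_means=means, differences=diffs,
                              frobenius=frob)


# -------------------------------------------------------------------- sweeps
SWEEP_GRIDS = {
    "K": (1, 5, 10, 20, 50),
    "n": (1, 2, 4, 8, 16),
    "lambda": (0.1, 0.3, 0.5, 0.7, 0.9),
}


def run_sweep(param: str, dataset, dist_graph: PredefinedGraph,
              model_cfg: ModelConfig, train_cfg: TrainConfig,
              values=None) -> list[dict]:
    """Train/evaluate once per grid value of K, n or lambda."""
    if param not in SWEEP_GRIDS:
        raise ValueError(f"unknown sweep parameter {param!r}")
    rows = []
    for value in (SWEEP_GRIDS[param] if values is None else values):
        cfg = copy.deepcopy(model_cfg)
        if param == "K":
            cfg.window_K = int(value)
        elif param == "n":
            cfg.avg_steps_n = int(value)
        else:
            cfg.lambda_ = float(value)
        model = DTGCN(cfg, dist_graph)
        trainer = Trainer(model, train_cfg)
        history = trainer.train(dataset.train, dataset.val)
        report = evaluate(trainer, dataset.test)
        row = {"param": param, "value": value,
               "epochs": len(history.epochs),
               "weighted_f1": report.weighted_f1}
        if report.auroc is not None:
            row["auroc"] = report.auroc
        rows.append(row)
    return rows
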