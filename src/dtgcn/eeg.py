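"""EEG containers, resampling, clip slicing and the electrode-distance graph.

Records carry a per-time-step binary seizure annotation (``fine_labels``)
alongside the usual (time x channel) signal matrix; clips derive their
single seizure/non-seizure label from it.  The predefined inter-channel
graph is a thresholded Gaussian kernel on Euclidean electrode distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
from fractions import Fraction
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

SEIZURE_CLASSES = ("none", "CF", "GN", "AB", "CT")

#: 19-channel subset of the international 10-20 montage.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)


# --------------------------------------------------------------------- types
@dataclass
class EEGRecord:
    """A continuous multichannel recording with per-step seizure labels."""

    signal: np.ndarray          # [N_total x M], microvolts
    fs: float                   # sampling frequency, Hz
    channel_names: list[str]
    fine_labels: np.ndarray     # [N_total] in {0,1}
    seizure_class: str = "none"
    record_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.fine_labels = np.asarray(self.fine_labels)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (time x channel) matrix")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.signal.shape[1] < 1:
            raise ValueError("need at least one channel")
        if self.signal.shape[0] != self.fine_labels.shape[0]:
            raise ValueError("fine_labels length must equal signal row count")
        if not np.isin(self.fine_labels, (0, 1)).all():
            raise ValueError("fine_labels must be binary")
        if self.seizure_class not in SEIZURE_CLASSES:
            raise ValueError(f"unknown seizure class {self.seizure_class!r}")
        self.fine_labels = self.fine_labels.astype(np.int8)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def n_steps(self) -> int:
        return self.signal.shape[0]


@dataclass
class EEGClip:
    """A fixed-length slice of a record; the model's unit of input."""

    signal: np.ndarray          # [N x M]
    fine_labels: np.ndarray     # [N]
    coarse_label: int           # 1 iff any fine label is 1
    seizure_class: str = "none"
    clip_seconds: float = 12.0
    fs: float = 200.0
    parent_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.fine_labels = np.asarray(self.fine_labels, dtype=np.int8)
        if self.signal.shape[0] != self.fine_labels.shape[0]:
            raise ValueError("fine_labels length must equal signal row count")
        if self.coarse_label != int(self.fine_labels.max(initial=0) > 0):
            raise ValueError("coarse_label inconsistent with fine_labels")


@dataclass
class ElectrodeLayout:
    """Named scalp electrodes at unit-sphere positions."""

    names: list[str]
    coords: np.ndarray          # [M x 3]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if len(self.names) != len(set(self.names)):
            raise ValueError("electrode names must be unique")
        if self.coords.shape != (len(self.names), 3):
            raise ValueError("coords must be [M x 3]")


@dataclass
class PredefinedGraph:
    """Static distance-derived adjacency over the electrode set."""

    weights: np.ndarray         # [M x M], entries in [0,1], symmetric
    kernel_sigma: float
    threshold_kappa: float

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------- operations
def derive_coarse_label(fine_labels: np.ndarray) -> int:
    """A clip is seizure (1) iff any of its time steps is seizure."""
    fine_labels = np.asarray(fine_labels)
    if fine_labels.size == 0:
        raise ValueError("fine_labels must be non-empty")
    if not np.isin(fine_labels, (0, 1)).all():
        raise ValueError("fine_labels must be binary")
    return int(fine_labels.max())


def resample_signal(record: EEGRecord, target_fs: float) -> EEGRecord:
    """Resample to ``target_fs``; labels follow by nearest-neighbor index map."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == record.fs:
        return replace(record)
    frac = Fraction(target_fs / record.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    sig = resample_poly(record.signal, up, down, axis=0)
    n_new = int(round(record.n_steps * target_fs / record.fs))
    sig = sig[:n_new]
    if sig.shape[0] < n_new:  # pad edge if polyphase output ran short
        sig = np.vstack([sig, np.repeat(sig[-1:], n_new - sig.shape[0], axis=0)])
    src = np.clip(np.round(np.arange(n_new) * record.fs / target_fs).astype(int),
                  0, record.n_steps - 1)
    labels = record.fine_labels[src]
    return replace(record, signal=sig, fs=float(target_fs), fine_labels=labels)


def slice_clips(record: EEGRecord, clip_seconds: float) -> list[EEGClip]:
    """Cut non-overlapping clips of clip_seconds; drop the trailing remainder.

    Clips are half-open index intervals [start, start + N).  A clip whose
    steps are all non-seizure gets coarse_label 0 and class "none" even
    inside a seizure-class record.
    """
    n_per_clip = int(round(clip_seconds * record.fs))
    if n_per_clip < 1:
        raise ValueError("clip_seconds x fs must be >= 1")
    n_clips = record.n_steps // n_per_clip
    if n_clips == 0:
        logger.warning("record %s shorter than one %gs clip; returning no clips",
                       record.record_id, clip_seconds)
        return []
    clips = []
    for k in range(n_clips):
        sl = slice(k * n_per_clip, (k + 1) * n_per_clip)
        fine = record.fine_labels[sl]
        coarse = derive_coarse_label(fine)
        clips.append(EEGClip(
            signal=record.signal[sl],
            fine_labels=fine,
            coarse_label=coarse,
            seizure_class=record.seizure_class if coarse else "none",
            clip_seconds=clip_seconds,
            fs=record.fs,
            parent_id=record.record_id,
        ))
    return clips


def build_dist_graph(layout: ElectrodeLayout, sigma: float | None = None,
                     kappa: float = 0.9) -> PredefinedGraph:
    """Gaussian-kernel adjacency exp(-d^2/sigma^2), thresholded at kappa.

    ``sigma`` defaults to the standard deviation of the pairwise Euclidean
    distances.  Entries below ``kappa`` are zeroed; the diagonal is the
    kernel value at distance zero (1).
    """
    coords = layout.coords
    m = coords.shape[0]
    if m < 2:
        raise ValueError("need at least two electrodes")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if sigma is None:
        iu = np.triu_indices(m, k=1)
        sigma = float(np.std(d[iu]))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = np.exp(-(d ** 2) / sigma ** 2)
    w[w < kappa] = 0.0
    off_diag = w.copy()
    np.fill_diagonal(off_diag, 0.0)
    if not off_diag.any():
        raise ValueError("kappa too large: thresholding left no edges")
    return PredefinedGraph(weights=w, kernel_sigma=sigma, threshold_kappa=kappa)


def normalized_adjacency(weights: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self loops: D^-1/2 (W + I) D^-1/2."""
    w = np.asarray(weights, dtype=np.float64)
    a = w + np.eye(w.shape[0])
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return a * dinv[:, None] * dinv[None, :]


# ----------------------------------------------------------- layout file I/O
def read_layout(path) -> ElectrodeLayout:
    """Read a plain-text electrode table: name x y z, one row each."""
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return ElectrodeLayout(names=names, coords=np.array(rows))


def write_layout(path, layout: ElectrodeLayout) -> None:
    with open(path, "w") as fh:
        fh.write("# name x y z\n")
        for name, (x, y, z) in zip(layout.names, layout.coords):
            fh.write(f"{name} {x:.10f} {y:.10f} {z:.10f}\n")


# -------------------------------------------------------------- EDF reading
def read_edf(path, channel_names: Sequence[str] = CHANNELS_1020) -> EEGRecord:
    """Read an EDF file, matching channels to ``channel_names``.

    EDF labels are matched case-insensitively by substring (clinical files
    use labels like "EEG FP1-REF").  All requested channels must be present
    and share one sampling rate.  Fine labels are initialized to zero; EDF
    carries no per-step seizure annotation.
    """
    from .edf import read_edf_signals

    labels, fs_per_chan, signals = read_edf_signals(path)
    idx = []
    for want in channel_names:
        matches = [i for i, lab in enumerate(labels) if want.lower() in lab.lower()]
        if not matches:
            raise ValueError(f"EDF file missing channel {want!r}")
        idx.append(matches[0])
    fs_set = {fs_per_chan[i] for i in idx}
    if len(fs_set) != 1:
        raise ValueError("selected channels have differing sampling rates")
    fs = fs_set.pop()
    sig = np.column_stack([signals[i] for i in idx])
    return EEGRecord(
        signal=sig, fs=fs, channel_names=list(channel_names),
        fine_labels=np.zeros(sig.shape[0], dtype=np.int8),
        record_id=str(path),
    )


# ------------------------------------------------------------ HDF5 clip sets
def write_clipset(path, clips: Sequence[EEGClip]) -> None:
    """Write clips to an HDF5 container (lossless round trip)."""
    if not clips:
        raise ValueError("no clips to write")
    n = clips[0].signal.shape[0]
    if any(c.signal.shape != clips[0].signal.shape for c in clips):
        raise ValueError("all clips must share one shape")
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=np.stack([c.signal for c in clips]))
        f.create_dataset("fine_labels",
                         data=np.stack([c.fine_labels for c in clips]).astype(np.int8))
        f.create_dataset("class", data=np.array(
            [SEIZURE_CLASSES.index(c.seizure_class) for c in clips], dtype=np.int8))
        dt = h5py.string_dtype()
        f.create_dataset("parent_id",
                         data=np.array([c.parent_id for c in clips], dtype=dt))
        f.attrs["fs"] = clips[0].fs
        f.attrs["clip_seconds"] = clips[0].clip_seconds
        f.attrs["n_steps"] = n


def read_clipset(path) -> list[EEGClip]:
    with h5py.File(path, "r") as f:
        signal = f["signal"][...]
        fine = f["fine_labels"][...]
        cls = f["class"][...]
        parent = [p.decode() if isinstance(p, bytes) else str(p)
                  for p in f["parent_id"][...]]
        fs = float(f.attrs["fs"])
        clip_seconds = float(f.attrs["clip_seconds"])
    return [
        EEGClip(signal=signal[i], fine_labels=fine[i],
                coarse_label=derive_coarse_label(fine[i]) if fine[i].size else 0,
                seizure_class=SEIZURE_CLASSES[cls[i]],
                clip_seconds=clip_seconds, fs=fs, parent_id=parent[i])
        for i in range(signal.shape[0])
    ]
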