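"""Synthetic multichannel EEG with per-step seizure labels and planted
dynamic connectivity.

Records are 19-channel 10-20 montage signals: 1/f-shaped background noise
plus a 10 Hz rhythm, mixed through a baseline inter-channel coupling
matrix.  A seizing record carries one contiguous seizure interval whose
activity and coupling depend on the seizure class:

* CF — high-amplitude 3 Hz oscillation on a focal channel subset, with
  coupling strengthened only inside that subset;
* GN — 3 Hz on all channels with globally strengthened coupling;
* AB — brief spike-and-wave bursts (3 Hz with sharp harmonics) everywhere;
* CT — a 10 Hz tonic segment followed by amplitude-modulated 3 Hz clonic
  bursting, everywhere.

Fine-grained labels are 1 exactly on the seizure interval, so every stage
of the pipeline is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .eeg import (CHANNELS_1020, EEGClip, EEGRecord, ElectrodeLayout,
                  build_dist_graph, slice_clips)

_DEFAULT_MIX = {"none": 0.28, "CF": 0.18, "GN": 0.18, "AB": 0.18, "CT": 0.18}


@dataclass
class SynthConfig:
    n_channels: int = 19
    fs: float = 64.0
    record_seconds: float = 24.0
    class_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    seizure_duration: tuple[float, float] = (6.0, 12.0)
    absence_duration: tuple[float, float] = (3.0, 6.0)
    focal_channel_count: int = 4
    base_coupling: float = 0.15
    coupling_strength: float = 0.6
    background_amplitude: float = 15.0
    rhythm_amplitude: float = 10.0
    seizure_amplitude: float = 80.0
    snr: float = 8.0
    amplitude_matched: bool = False   # seizure visible only through coupling
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_mix probabilities must sum to 1")
        if self.seizure_duration[1] >= self.record_seconds:
            raise ValueError("seizure_duration must be shorter than the record")


@dataclass
class SynthRecord:
    """An EEGRecord plus the ground truth the generator planted."""

    record: EEGRecord
    seizure_start: int          # step index, half-open interval
    seizure_end: int
    involved_channels: np.ndarray
    coupling_baseline: np.ndarray
    coupling_seizure: np.ndarray | None


# ------------------------------------------------------------------- layout
def standard_1020_layout() -> ElectrodeLayout:
    """Unit-sphere positions for the 19-channel 10-20 montage.

    Built from the montage's arc geometry (x right, y anterior, z up):
    midline and temporal rows at 20%/40% of the nasion-inion half-circle,
    the circumferential ring at 10% steps, and F3/F4, P3/P4 as spherical
    midpoints of their neighboring ring/midline sites.
    """
    s36, c36 = np.sin(np.radians(36)), np.cos(np.radians(36))
    s72, c72 = np.sin(np.radians(72)), np.cos(np.radians(72))

    def ring(beta_deg: float, side: int) -> np.ndarray:
        b = np.radians(beta_deg)
        return np.array([side * s72 * np.sin(b), s72 * np.cos(b), c72])

    def mid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        v = (a + b) / 2.0
        return v / np.linalg.norm(v)

    pos = {
        "Cz": np.array([0.0, 0.0, 1.0]),
        "Fz": np.array([0.0, s36, c36]),
        "Pz": np.array([0.0, -s36, c36]),
        "C3": np.array([-s36, 0.0, c36]),
        "C4": np.array([s36, 0.0, c36]),
        "T3": np.array([-s72, 0.0, c72]),
        "T4": np.array([s72, 0.0, c72]),
        "Fp1": ring(18, -1), "Fp2": ring(18, +1),
        "F7": ring(54, -1), "F8": ring(54, +1),
        "T5": ring(126, -1), "T6": ring(126, +1),
        "O1": ring(162, -1), "O2": ring(162, +1),
    }
    pos["F3"] = mid(pos["Fz"], pos["F7"])
    pos["F4"] = mid(pos["Fz"], pos["F8"])
    pos["P3"] = mid(pos["Pz"], pos["T5"])
    pos["P4"] = mid(pos["Pz"], pos["T6"])
    names = list(CHANNELS_1020)
    return ElectrodeLayout(names=names, coords=np.stack([pos[n] for n in names]))


# ------------------------------------------------------------------ signals
def _pink_noise(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """1/f-shaped noise: white noise through a leaky cumulative filter."""
    white = rng.standard_normal((n, m))
    shaped = lfilter([1.0], [1.0, -0.9], white, axis=0)
    return shaped / shaped.std(axis=0, keepdims=True)


def _global_coupling(m: int, strength: float) -> np.ndarray:
    return (1.0 - strength) * np.eye(m) + strength * np.full((m, m), 1.0 / m)


def _focal_coupling(m: int, channels: np.ndarray, strength: float) -> np.ndarray:
    a = np.eye(m)
    k = len(channels)
    for i in channels:
        a[i, i] = 1.0 - strength
        for j in channels:
            a[i, j] += strength / k
    return a


def _spike_wave(phase: np.ndarray) -> np.ndarray:
    """3 Hz wave with sharp harmonics (spike-and-wave caricature)."""
    return np.sin(phase) + 0.6 * np.sin(2 * phase) + 0.35 * np.sin(3 * phase)


def generate_record(cfg: SynthConfig, seizure_class: str | None = None,
                    seed: int | None = None, record_id: str = "") -> SynthRecord:
    """One synthetic record; deterministic for a given (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if seizure_class is None:
        classes = sorted(cfg.class_mix)
        probs = np.array([cfg.class_mix[c] for c in classes])
        seizure_class = str(rng.choice(classes, p=probs))
    if seizure_class not in ("none", "CF", "GN", "AB", "CT"):
        raise ValueError(f"invalid seizure class {seizure_class!r}")
    n = int(round(cfg.record_seconds * cfg.fs))
    m = cfg.n_channels
    t = np.arange(n) / cfg.fs

    layout = standard_1020_layout() if m == 19 else None
    if layout is not None:
        # kappa=0.1 keeps ~3 neighbors per electrode on the unit sphere
        w = build_dist_graph(layout, kappa=0.1).weights.copy()
        np.fill_diagonal(w, 0.0)
        w = w / max(w.sum(axis=1).max(), 1e-12)
    else:
        w = np.zeros((m, m))
    a_base = (1.0 - cfg.base_coupling) * np.eye(m) + cfg.base_coupling * w

    src = cfg.background_amplitude * _pink_noise(rng, n, m)
    phases = rng.uniform(0, 2 * np.pi, size=m)
    src += cfg.rhythm_amplitude * np.sin(2 * np.pi * 10.0 * t[:, None] + phases)

    fine = np.zeros(n, dtype=np.int8)
    start = end = 0
    involved = np.array([], dtype=int)
    a_seiz = None
    if seizure_class != "none":
        lo, hi = (cfg.absence_duration if seizure_class == "AB"
                  else cfg.seizure_duration)
        dur = int(round(rng.uniform(lo, hi) * cfg.fs))
        dur = min(dur, n - 1)
        start = int(rng.integers(0, n - dur))
        end = start + dur
        fine[start:end] = 1
        ts = t[start:end, None]
        amp = (cfg.rhythm_amplitude if cfg.amplitude_matched
               else cfg.seizure_amplitude)
        ph3 = 2 * np.pi * 3.0 * ts + phases
        if seizure_class == "CF":
            involved = rng.choice(m, size=cfg.focal_channel_count, replace=False)
            burst = amp * np.sin(ph3[:, involved])
            src[start:end, involved] += burst
            a_seiz = _focal_coupling(m, involved, cfg.coupling_strength) @ a_base
        elif seizure_class == "GN":
            involved = np.arange(m)
            # phase-coherent across channels: generalized discharges
            src[start:end] += amp * np.sin(2 * np.pi * 3.0 * ts)
            a_seiz = _global_coupling(m, cfg.coupling_strength) @ a_base
        elif seizure_class == "AB":
            involved = np.arange(m)
            # brief, high-amplitude spike-and-wave, phase-coherent
            src[start:end] += 1.4 * amp * _spike_wave(2 * np.pi * 3.0 * ts)
            a_seiz = _global_coupling(m, 0.5 * cfg.coupling_strength) @ a_base
        else:  # CT: tonic 10 Hz then clonic 3 Hz bursting
            involved = np.arange(m)
            half = dur // 2
            tonic = 1.2 * amp * np.sin(2 * np.pi * 10.0 * ts[:half] + phases)
            envelope = (np.sin(2 * np.pi * 1.0 * ts[half:]) > 0).astype(float)
            clonic = amp * np.sin(ph3[half:]) * envelope
            src[start:end][:half] += tonic
            src[start:end][half:] += clonic
            a_seiz = _global_coupling(m, 0.7 * cfg.coupling_strength) @ a_base

    out = src @ a_base.T
    if a_seiz is not None:
        out[start:end] = src[start:end] @ a_seiz.T
    out += (cfg.background_amplitude / cfg.snr) * rng.standard_normal((n, m))

    names = list(CHANNELS_1020) if m == 19 else [f"ch{i}" for i in range(m)]
    record = EEGRecord(signal=out, fs=cfg.fs, channel_names=names,
                       fine_labels=fine, seizure_class=seizure_class,
                       record_id=record_id or f"synth-{seed}")
    return SynthRecord(record=record, seizure_start=start, seizure_end=end,
                       involved_channels=involved, coupling_baseline=a_base,
                       coupling_seizure=a_seiz)


# ------------------------------------------------------------------ dataset
@dataclass
class ClipDataset:
    train: list[EEGClip]
    val: list[EEGClip]
    test: list[EEGClip]
    records: list[SynthRecord] = field(default_factory=list)


def generate_dataset(cfg: SynthConfig, n_records: int,
                     split_ratio: float = 0.9, test_fraction: float = 0.2,
                     clip_seconds: float = 12.0) -> ClipDataset:
    """Generate records, slice clips, split 9:1 train:val at record level.

    A disjoint ``test_fraction`` of the records is held out first; no
    record contributes clips to more than one split.
    """
    if n_records < 10:
        raise ValueError("need at least 10 records")
    rng = np.random.default_rng(cfg.seed)
    records = [generate_record(cfg, seed=int(rng.integers(2 ** 31)),
                               record_id=f"rec{i:04d}")
               for i in range(n_records)]
    order = rng.permutation(n_records)
    n_test = int(round(test_fraction * n_records))
    test_idx = set(order[:n_test].tolist())
    pool = [i for i in order.tolist() if i not in test_idx]
    n_train = int(round(split_ratio * len(pool)))
    train_idx = set(pool[:n_train])

    def clips_of(indices) -> list[EEGClip]:
        out = []
        for i in sorted(indices):
            out.extend(slice_clips(records[i].record, clip_seconds))
        return out

    return ClipDataset(train=clips_of(train_idx),
                       val=clips_of(set(pool) - train_idx),
                       test=clips_of(test_idx),
                       records=records)
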