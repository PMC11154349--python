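"""Minimal European Data Format (EDF) I/O.

Covers the plain 16-bit-integer EDF subset produced by clinical EEG
recorders: an ASCII header, per-signal headers, and little-endian int16
data records with linear physical scaling.  Annotations (EDF+) and
variable-rate signals are out of scope.
"""

from __future__ import annotations

import numpy as np

_HDR = 256
_SIG_FIELDS = (  # (width, key)
    (16, "label"), (80, "transducer"), (8, "dimension"),
    (8, "physical_min"), (8, "physical_max"),
    (8, "digital_min"), (8, "digital_max"),
    (80, "prefilter"), (8, "samples_per_record"), (32, "reserved"),
)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def read_edf_signals(path):
    """Return (labels, fs_per_channel, list of 1-D physical-unit signals)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HDR:
        raise ValueError("not an EDF file: truncated header")
    n_records = int(raw[236:244].decode("ascii").strip())
    record_dur = float(raw[244:252].decode("ascii").strip())
    ns = int(raw[252:256].decode("ascii").strip())
    if record_dur <= 0 or ns < 1:
        raise ValueError("invalid EDF header")
    off = _HDR
    fields: dict[str, list[str]] = {}
    for width, key in _SIG_FIELDS:
        vals = []
        for s in range(ns):
            vals.append(raw[off + s * width: off + (s + 1) * width].decode("ascii").strip())
        fields[key] = vals
        off += ns * width
    spr = [int(v) for v in fields["samples_per_record"]]
    pmin = [float(v) for v in fields["physical_min"]]
    pmax = [float(v) for v in fields["physical_max"]]
    dmin = [int(v) for v in fields["digital_min"]]
    dmax = [int(v) for v in fields["digital_max"]]
    data = np.frombuffer(raw[off:], dtype="<i2")
    per_rec = sum(spr)
    if data.size < n_records * per_rec:
        raise ValueError("EDF data section truncated")
    data = data[: n_records * per_rec].reshape(n_records, per_rec)
    signals, fs = [], []
    col = 0
    for s in range(ns):
        dig = data[:, col: col + spr[s]].reshape(-1).astype(np.float64)
        gain = (pmax[s] - pmin[s]) / (dmax[s] - dmin[s])
        signals.append((dig - dmin[s]) * gain + pmin[s])
        fs.append(spr[s] / record_dur)
        col += spr[s]
    return fields["label"], fs, signals


def write_edf(path, signal: np.ndarray, fs: float, labels: list[str],
              physical_range: tuple[float, float] | None = None) -> None:
    """Write a (time x channel) matrix as plain EDF (1-second records)."""
    signal = np.asarray(signal, dtype=np.float64)
    n, m = signal.shape
    if len(labels) != m:
        raise ValueError("one label per channel required")
    spr = int(round(fs))
    if spr != fs:
        raise ValueError("writer supports integer sampling rates only")
    n_records = n // spr
    if n_records < 1:
        raise ValueError("signal shorter than one data record")
    if physical_range is None:
        amp = float(np.abs(signal).max()) or 1.0
        physical_range = (-amp, amp)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    head = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate X", 80),
        _pad("01.01.20", 8), _pad("00.00.00", 8),
        _pad(str(_HDR + 256 * m), 8), _pad("", 44),
        _pad(str(n_records), 8), _pad("1", 8), _pad(str(m), 4),
    ])
    sig_head = b""
    values = {
        "label": labels, "transducer": [""] * m, "dimension": ["uV"] * m,
        "physical_min": [f"{pmin:.8g}"[:8]] * m, "physical_max": [f"{pmax:.8g}"[:8]] * m,
        "digital_min": [str(dmin)] * m, "digital_max": [str(dmax)] * m,
        "prefilter": [""] * m, "samples_per_record": [str(spr)] * m,
        "reserved": [""] * m,
    }
    for width, key in _SIG_FIELDS:
        for s in range(m):
            sig_head += _pad(str(values[key][s]), width)
    gain = (dmax - dmin) / (pmax - pmin)
    dig = np.clip(np.round((signal - pmin) * gain + dmin), dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(head + sig_head)
        for r in range(n_records):
            chunk = dig[r * spr:(r + 1) * spr]  # [spr x m]
            fh.write(chunk.T.tobytes())         # channel-sequential per record
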