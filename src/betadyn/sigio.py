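"""Recording container, CSV/EDF I/O and epoch selection.

Recordings are two-channel (MCx ECoG + STN LFP) resting-state field
potentials, but the container is generic over channel count. Time intervals
are half-open ``[start_s, end_s)`` with sample index ``floor(t * fs)``.

EDF support is a minimal implementation of the 16-bit European Data Format
(integer-second records, one record per second); no installed library writes
EDF, and the format's fixed ASCII header plus int16 payload is small enough to
carry here. CSV uses the dialect ``time_s,MCx,STN`` with full float precision,
so CSV round trips are exact while EDF round trips are exact to one
quantization step of the stored physical range.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Recording", "EpochSet", "read_recording", "write_recording", "select_epochs"]

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class Recording:
    """Multichannel field-potential recording with subject metadata."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs_hz: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    group_label: str = ""
    week: int = 0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown channel {label!r}; have {self.channel_labels}") from None


@dataclass
class EpochSet:
    """Non-overlapping half-open analysis windows within one recording."""

    epochs: list[tuple[float, float]]
    recording: Recording | None = None

    def __post_init__(self) -> None:
        eps = sorted(self.epochs)
        for (a0, a1), (b0, b1) in zip(eps, eps[1:]):
            if b0 < a1:
                raise ValueError("epochs must be non-overlapping")
        if self.recording is not None:
            for s, e in eps:
                if s < 0 or e > self.recording.duration_s + 1e-9:
                    raise ValueError(f"epoch [{s},{e}) outside recording bounds")
        self.epochs = eps

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def total_time_s(self) -> float:
        return sum(e - s for s, e in self.epochs)


# ---------------------------------------------------------------------------
# CSV

def _write_csv(rec: Recording, path: Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs_hz
    df = pd.DataFrame({"time_s": t})
    for lab, ch in zip(rec.channel_labels, rec.samples):
        df[lab] = ch
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs_hz:g} subject={rec.subject_id} "
                 f"group={rec.group_label} week={rec.week}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path) -> Recording:
    meta = {"subject": "", "group": "", "week": 0, "fs_hz": None}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            df = pd.read_csv(io.StringIO(first + fh.read()), float_precision="round_trip")
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError("CSV must have a time_s column plus channel columns")
    if df.isna().any().any():
        raise ValueError("inconsistent channel lengths (missing values in CSV)")
    labels = [c for c in df.columns if c != "time_s"]
    if meta["fs_hz"] is not None:
        fs = float(meta["fs_hz"])
    else:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    return Recording(
        samples=df[labels].to_numpy().T,
        fs_hz=fs,
        channel_labels=tuple(labels),
        subject_id=str(meta["subject"]),
        group_label=str(meta["group"]),
        week=int(meta["week"]),
    )


# ---------------------------------------------------------------------------
# EDF (16-bit, 1-s records)

def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field {value!r} exceeds {width} chars")
    return b.ljust(width)


def _phys_range(data: np.ndarray) -> float:
    """Symmetric physical range rounded so it fits an 8-char EDF field exactly."""
    m = float(np.max(np.abs(data))) if data.size else 1.0
    if m == 0:
        m = 1.0
    # round UP to 4 significant digits so the stored string reproduces the
    # float used for scaling and still covers the data
    from math import ceil, floor, log10
    exp = floor(log10(m))
    pm = ceil(m / 10.0 ** (exp - 3)) * 10.0 ** (exp - 3)
    return float(f"{pm:.6g}")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = int(round(rec.fs_hz))
    if abs(fs - rec.fs_hz) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if rec.n_samples % fs != 0:
        raise ValueError("EDF writer requires a whole number of 1-s records")
    n_rec = rec.n_samples // fs
    ns = len(rec.channel_labels)
    patient = f"{rec.subject_id or 'X'} {rec.group_label or 'X'} week={rec.week}"
    hdr = b"".join([
        _ascii("0", 8),
        _ascii(patient[:80], 80),
        _ascii("betadyn synthetic recording", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(str(256 * (ns + 1)), 8),
        _ascii("", 44),
        _ascii(str(n_rec), 8),
        _ascii("1", 8),
        _ascii(str(ns), 4),
    ])
    pmaxs = [_phys_range(ch) for ch in rec.samples]
    sig = b"".join([
        b"".join(_ascii(lab, 16) for lab in rec.channel_labels),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii("uV", 8) for _ in range(ns)),
        b"".join(_ascii(f"{-pm:.6g}", 8) for pm in pmaxs),
        b"".join(_ascii(f"{pm:.6g}", 8) for pm in pmaxs),
        b"".join(_ascii(str(_DIG_MIN), 8) for _ in range(ns)),
        b"".join(_ascii(str(_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii(str(fs), 8) for _ in range(ns)),
        b"".join(_ascii("", 32) for _ in range(ns)),
    ])
    digital = []
    for ch, pm in zip(rec.samples, pmaxs):
        gain = 2.0 * pm / (_DIG_MAX - _DIG_MIN)
        d = np.clip(np.round((ch + pm) / gain) + _DIG_MIN, _DIG_MIN, _DIG_MAX)
        digital.append(d.astype("<i2"))
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r * fs:(r + 1) * fs].tobytes())


def _read_edf(path: Path) -> Recording:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise ValueError("not an EDF file (truncated header)")
    def f(off, width):
        return raw[off:off + width].decode("ascii", errors="replace").strip()
    patient = f(8, 80)
    n_rec = int(f(236, 8))
    rec_dur = float(f(244, 8))
    ns = int(f(252, 4))
    base = 256
    def sf(block_off, width, i):
        return f(base + block_off * ns + width * i, width)
    labels, pmins, pmaxs, dmins, dmaxs, nsamp = [], [], [], [], [], []
    off = 0
    for width, dest, cast in [
        (16, labels, str), (80, None, str), (8, None, str),
        (8, pmins, float), (8, pmaxs, float), (8, dmins, float),
        (8, dmaxs, float), (80, None, str), (8, nsamp, int), (32, None, str),
    ]:
        for i in range(ns):
            v = f(base + off + width * i, width)
            if dest is not None:
                dest.append(cast(v))
        off += width * ns
    if len(set(labels)) != ns:
        raise ValueError(f"duplicate or unknown channel labels in EDF: {labels}")
    data_off = base + off
    payload = np.frombuffer(raw, dtype="<i2", offset=data_off)
    per_rec = sum(nsamp)
    if payload.size < n_rec * per_rec:
        raise ValueError("EDF payload shorter than the header promises")
    payload = payload[: n_rec * per_rec].reshape(n_rec, per_rec)
    chans = []
    pos = 0
    for i in range(ns):
        d = payload[:, pos:pos + nsamp[i]].reshape(-1).astype(float)
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        chans.append(pmins[i] + gain * (d - dmins[i]))
        pos += nsamp[i]
    if len({c.size for c in chans}) != 1:
        raise ValueError("inconsistent channel lengths in EDF")
    fs = nsamp[0] / rec_dur
    sub, grp, week = "", "", 0
    toks = patient.split()
    if len(toks) >= 3 and toks[-1].startswith("week="):
        sub, grp, week = toks[0], toks[1], int(toks[-1][5:])
    return Recording(
        samples=np.vstack(chans), fs_hz=fs, channel_labels=tuple(labels),
        subject_id=sub if sub != "X" else "", group_label=grp if grp != "X" else "",
        week=week,
    )


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'edf'")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'edf'")


# ---------------------------------------------------------------------------
# Epoch selection

def select_epochs(
    rec: Recording,
    n_epochs: int = 3,
    epoch_s: float = 30.0,
    artifact_k: float = 6.0,
) -> EpochSet:
    """Earliest n_epochs artifact-free windows of epoch_s seconds.

    A sample is an artifact if, on any channel, |x - median| exceeds
    ``artifact_k`` robust SDs (1.4826 * MAD). Candidate windows start on the
    1-s grid; the earliest clean, non-overlapping windows win. This automates
    the visual artifact screening used when epochs are marked by hand.
    """
    if rec.duration_s + 1e-9 < n_epochs * epoch_s:
        raise ValueError(
            f"recording of {rec.duration_s:g} s cannot hold {n_epochs} x {epoch_s:g} s epochs"
        )
    med = np.median(rec.samples, axis=1, keepdims=True)
    mad = np.median(np.abs(rec.samples - med), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf  # flat channel: nothing is an artifact
    bad = np.any(np.abs(rec.samples - med) > artifact_k * robust_sd, axis=0)
    fs = rec.fs_hz
    win_n = int(round(epoch_s * fs))
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    epochs: list[tuple[float, float]] = []
    t = 0.0
    while len(epochs) < n_epochs:
        i0 = int(np.floor(t * fs))
        i1 = i0 + win_n
        if i1 > rec.n_samples:
            break
        if bad_cum[i1] - bad_cum[i0] == 0:
            epochs.append((t, t + epoch_s))
            t += epoch_s
        else:
            t += 1.0
    if len(epochs) < n_epochs:
        raise ValueError(
            f"only {len(epochs)} clean {epoch_s:g}-s windows found, {n_epochs} required"
        )
    return EpochSet(epochs=epochs, recording=rec)
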