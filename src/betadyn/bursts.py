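"""Beta-burst detection and burst-dynamics statistics.

Pipeline: z-score the raw channel, compute per-frequency Morlet wavelet power
(10 cycles per frequency on the integer 1 Hz grid), average power over the
target band to obtain one envelope sample per input sample, threshold the
envelope at the 75th percentile of samples pooled across all signals of a
region, and keep supra-threshold runs lasting at least 100 ms as bursts.
Bursts longer than 350 ms count as "long". Amplitude is the per-burst peak
envelope (in z-power units) averaged across bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .spectral import BandDefinition, HIGH_BETA

__all__ = [
    "BurstConfig",
    "Burst",
    "BurstSet",
    "BurstStats",
    "zscore",
    "band_envelope",
    "pooled_threshold",
    "detect_bursts",
    "burst_stats",
]


@dataclass(frozen=True)
class BurstConfig:
    """Detection parameters.

    The wavelet frequency grid runs 1..128 Hz at 1 Hz resolution; envelopes are
    only computed on the band's integer frequencies, and bands above 100 Hz
    trigger a warning because 128 Hz is the Nyquist frequency at fs = 256 Hz.
    """

    wavelet_cycles: int = 10
    freq_grid_hz: tuple[int, int] = (1, 128)
    band: BandDefinition = HIGH_BETA
    threshold_quantile: float = 0.75
    min_duration_s: float = 0.100
    long_duration_s: float = 0.350

    def __post_init__(self) -> None:
        if not 0 < self.threshold_quantile < 1:
            raise ValueError("threshold_quantile must be in (0, 1)")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")
        if self.long_duration_s <= self.min_duration_s:
            raise ValueError("long_duration_s must exceed min_duration_s")


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    peak_envelope: float
    mean_envelope: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BurstSet:
    bursts: list[Burst]
    threshold_used: float
    source: str = ""

    def __post_init__(self) -> None:
        self.bursts = sorted(self.bursts, key=lambda b: b.start_s)
        for a, b in zip(self.bursts, self.bursts[1:]):
            if b.start_s < a.end_s:
                raise ValueError("bursts must be non-overlapping")

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([b.duration_s for b in self.bursts])


@dataclass(frozen=True)
class BurstStats:
    """amplitude: mean per-burst peak envelope; rate: bursts/min;
    long_burst_prob: % of bursts longer than the long-burst cutoff."""

    amplitude: float
    rate: float
    long_burst_prob: float
    n_bursts: int


def zscore(x: np.ndarray) -> np.ndarray:
    """(x - mean) / population SD; rejects constant signals."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("z-score needs at least 2 samples")
    sd = x.std()  # population SD (ddof=0)
    if sd == 0:
        raise ValueError("z-score undefined for a constant signal")
    return (x - x.mean()) / sd


def _morlet_kernel(freq_hz: float, fs_hz: float, n_cycles: int) -> np.ndarray:
    """Unit-energy complex Morlet wavelet, support +-5 temporal SDs."""
    sd_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(5.0 * sd_t * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    gauss = np.exp(-(t**2) / (2.0 * sd_t**2))
    norm = 1.0 / np.sqrt(sd_t * np.sqrt(np.pi) * fs_hz)
    return norm * gauss * np.exp(2j * np.pi * freq_hz * t)


def band_envelope(x: np.ndarray, fs_hz: float, cfg: BurstConfig | None = None) -> np.ndarray:
    """Band-mean Morlet power envelope of a z-scored signal.

    Wavelet power (squared magnitude of the complex convolution) is computed at
    every integer frequency of ``cfg.band`` and averaged across frequencies,
    giving one non-negative envelope sample per input sample.
    """
    cfg = cfg or BurstConfig()
    x = np.asarray(x, dtype=float)
    lo, hi = int(np.ceil(cfg.band.lo_hz)), int(np.floor(cfg.band.hi_hz))
    glo, ghi = cfg.freq_grid_hz
    if lo < glo or hi > ghi:
        raise ValueError(f"band [{lo},{hi}] outside the {glo}-{ghi} Hz wavelet grid")
    if hi > fs_hz / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {fs_hz / 2:g} Hz")
    if hi > 100:
        warnings.warn(
            f"band reaches {hi} Hz; at fs={fs_hz:g} the 1-128 Hz grid touches "
            "Nyquist and estimates above 100 Hz are unreliable"
        )
    env = np.zeros_like(x)
    for f in range(lo, hi + 1):
        w = _morlet_kernel(float(f), fs_hz, cfg.wavelet_cycles)
        env += np.abs(sps.fftconvolve(x, w, mode="same")) ** 2
    return env / (hi - lo + 1)


def pooled_threshold(envelopes: Iterable[np.ndarray], quantile: float = 0.75) -> float:
    """Linear-interpolation percentile of all envelope samples pooled.

    One common threshold per region: the pool spans every subject, group and
    week of that region, as a single concatenated sample.
    """
    pool = [np.ravel(np.asarray(e, dtype=float)) for e in envelopes]
    if not pool or sum(p.size for p in pool) == 0:
        raise ValueError("empty envelope pool")
    return float(np.percentile(np.concatenate(pool), quantile * 100.0, method="linear"))


def detect_bursts(
    envelope: np.ndarray,
    threshold: float,
    fs_hz: float,
    cfg: BurstConfig | None = None,
    t_offset_s: float = 0.0,
    source: str = "",
) -> BurstSet:
    """Maximal strictly-supra-threshold runs lasting >= min_duration_s.

    Runs touching the first or last envelope sample are discarded (their true
    extent is unknown at an epoch boundary, and truncation would bias durations
    downwards). Burst intervals are half-open: start at the first
    supra-threshold sample, end one sample past the last, so duration is
    run_length / fs.
    """
    cfg = cfg or BurstConfig()
    env = np.asarray(envelope, dtype=float)
    above = env > threshold
    # run boundaries via sign changes of the padded mask
    d = np.diff(above.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # one past last supra sample
    bursts = []
    min_n = int(np.ceil(cfg.min_duration_s * fs_hz - 1e-9))
    for i0, i1 in zip(starts, ends):
        if i0 == 0 or i1 == env.size:
            continue  # clipped by the epoch edge
        if i1 - i0 < min_n:
            continue
        seg = env[i0:i1]
        bursts.append(
            Burst(
                start_s=t_offset_s + i0 / fs_hz,
                end_s=t_offset_s + i1 / fs_hz,
                peak_envelope=float(seg.max()),
                mean_envelope=float(seg.mean()),
            )
        )
    return BurstSet(bursts=bursts, threshold_used=float(threshold), source=source)


def burst_stats(
    bs: BurstSet | Sequence[BurstSet],
    total_time_s: float,
    long_duration_s: float = 0.350,
) -> BurstStats:
    """Summary statistics over one or several (e.g. per-epoch) burst sets.

    With zero bursts the rate is 0 and amplitude / long-burst probability are
    undefined (NaN). "Long" is read strictly: duration > long_duration_s.
    """
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    sets = [bs] if isinstance(bs, BurstSet) else list(bs)
    bursts = [b for s in sets for b in s.bursts]
    n = len(bursts)
    rate = 60.0 * n / total_time_s
    if n == 0:
        return BurstStats(amplitude=float("nan"), rate=0.0, long_burst_prob=float("nan"), n_bursts=0)
    amp = float(np.mean([b.peak_envelope for b in bursts]))
    lbp = 100.0 * sum(b.duration_s > long_duration_s for b in bursts) / n
    return BurstStats(amplitude=amp, rate=rate, long_burst_prob=lbp, n_bursts=n)
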