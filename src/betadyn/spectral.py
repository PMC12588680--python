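"""Power spectra at 1 Hz resolution and beta-band summaries.

Spectra are averages of Hann-windowed periodograms over non-overlapping 1-s
windows (one window per second of every analysis epoch), which yields exactly
1 Hz frequency bins. Absolute spectra are normalized to the summed power over
5-45 and 55-95 Hz — the 46-54 Hz gap excludes the 50 Hz mains region — before
band means are taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "PowerSpectrum",
    "TOTAL_BETA",
    "HIGH_BETA",
    "LOW_BETA",
    "NORM_BANDS",
    "periodogram_hann",
    "normalize_spectrum",
    "band_mean",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive integer-bin endpoints."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if self.lo_hz > self.hi_hz:
            raise ValueError(f"band {self.name}: lo {self.lo_hz} > hi {self.hi_hz}")


#: Canonical beta sub-bands. Low and high beta partition total beta on the
#: integer 1 Hz grid (bins 13..20 and 21..30).
TOTAL_BETA = BandDefinition("total_beta", 13, 30)
HIGH_BETA = BandDefinition("high_beta", 21, 30)
LOW_BETA = BandDefinition("low_beta", 13, 20)

#: Normalization bands: power is expressed relative to the total over these.
NORM_BANDS = (BandDefinition("norm_lo", 5, 45), BandDefinition("norm_hi", 55, 95))


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    power: np.ndarray
    normalized: bool = False
    norm_bands: tuple = field(default=NORM_BANDS)

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")

    def band_indices(self, band: BandDefinition) -> np.ndarray:
        idx = np.flatnonzero((self.freqs_hz >= band.lo_hz) & (self.freqs_hz <= band.hi_hz))
        if idx.size == 0:
            raise ValueError(f"band {band.name} [{band.lo_hz},{band.hi_hz}] outside spectrum")
        return idx


def _epoch_slices(n_samples: int, fs: float, epochs: Sequence[tuple[float, float]] | None):
    """Sample index ranges for half-open [start_s, end_s) epochs."""
    if epochs is None:
        return [(0, n_samples)]
    out = []
    for start_s, end_s in epochs:
        i0, i1 = int(np.floor(start_s * fs)), int(np.floor(end_s * fs))
        if i0 < 0 or i1 > n_samples or i1 <= i0:
            raise ValueError(f"epoch [{start_s},{end_s}) outside recording")
        out.append((i0, i1))
    return out


def periodogram_hann(
    x: np.ndarray,
    fs_hz: float,
    epochs: Sequence[tuple[float, float]] | None = None,
) -> PowerSpectrum:
    """Average Hann periodogram over non-overlapping 1-s windows.

    Each window holds exactly ``fs_hz`` samples so bins fall on integer
    frequencies. Windows are mean-removed (the hardware high-pass leaves no
    trend worth detrending further). Power is scaled per 1 Hz bin with Hann
    window-power compensation, so the summed spectrum of a stationary signal
    tracks its variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single channel (1-D array)")
    nper = int(round(fs_hz))
    if abs(nper - fs_hz) > 1e-9:
        raise ValueError("sampling rate must be an integer number of samples per second")
    acc = None
    n_windows = 0
    for i0, i1 in _epoch_slices(x.size, fs_hz, epochs):
        seg = x[i0:i1]
        if seg.size < nper:
            raise ValueError("epoch shorter than the 1-s analysis window")
        nwin = seg.size // nper
        f, p = sps.welch(
            seg[: nwin * nper],
            fs=fs_hz,
            window="hann",
            nperseg=nper,
            noverlap=0,
            detrend="constant",
            scaling="density",
            average="mean",
        )
        acc = p * nwin if acc is None else acc + p * nwin
        n_windows += nwin
    assert acc is not None
    return PowerSpectrum(freqs_hz=f, power=acc / n_windows)


def normalize_spectrum(ps: PowerSpectrum) -> PowerSpectrum:
    """Divide by the summed power over the 5-45 and 55-95 Hz bands.

    Idempotent: normalizing a normalized spectrum renormalizes by 1.
    """
    idx = np.concatenate([ps.band_indices(b) for b in NORM_BANDS])
    total = float(ps.power[idx].sum())
    if total <= 0:
        raise ValueError("normalization sum over 5-45/55-95 Hz is zero")
    return replace(ps, power=ps.power / total, normalized=True)


def band_mean(ps: PowerSpectrum, band: BandDefinition) -> float:
    """Arithmetic mean of per-bin power over the band's inclusive bins."""
    return float(ps.power[ps.band_indices(band)].mean())
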