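"""Imaginary coherence between motor-cortex and subthalamic channels.

The imaginary part of coherency is insensitive to zero-lag coupling (volume
conduction / common reference), so a scaled copy of a signal produces exactly
zero while genuinely lagged interactions do not. Windows (1 s, Hann, zero
overlap) are pooled across all epochs before spectra are averaged, maximizing
the degrees of freedom of the estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .spectral import BandDefinition, PowerSpectrum, _epoch_slices, band_mean

__all__ = ["CoherenceSpectrum", "imaginary_coherence", "band_mean_coherence"]


@dataclass
class CoherenceSpectrum:
    freqs_hz: np.ndarray
    icoh: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.icoh = np.asarray(self.icoh, dtype=float)
        if self.freqs_hz.shape != self.icoh.shape:
            raise ValueError("freqs and icoh must have the same shape")
        if np.any(self.icoh < -1e-12) or np.any(self.icoh > 1 + 1e-9):
            raise ValueError("imaginary coherence must lie in [0, 1]")


def imaginary_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs_hz: float,
    epochs: Sequence[tuple[float, float]] | None = None,
) -> CoherenceSpectrum:
    """|Im C(f)| with C = S_xy / sqrt(S_xx S_yy), averaged over 1-s windows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("channels must be equal-length 1-D arrays")
    # |Im C| is symmetric in its arguments; canonicalize the operand order so
    # icoh(x, y) and icoh(y, x) are bit-identical, not merely close
    if x.tobytes() > y.tobytes():
        x, y = y, x
    nper = int(round(fs_hz))
    sxx = syy = None
    sxy = None
    n_windows = 0
    for i0, i1 in _epoch_slices(x.size, fs_hz, epochs):
        nwin = (i1 - i0) // nper
        if nwin == 0:
            raise ValueError("epoch shorter than the 1-s analysis window")
        sl = slice(i0, i0 + nwin * nper)
        kw = dict(fs=fs_hz, window="hann", nperseg=nper, noverlap=0,
                  detrend="constant", scaling="density", average="mean")
        f, pxx = sps.welch(x[sl], **kw)
        _, pyy = sps.welch(y[sl], **kw)
        _, pxy = sps.csd(x[sl], y[sl], **kw)
        if sxx is None:
            sxx, syy, sxy = pxx * nwin, pyy * nwin, pxy * nwin
        else:
            sxx += pxx * nwin
            syy += pyy * nwin
            sxy += pxy * nwin
        n_windows += nwin
    if n_windows < 2:
        raise ValueError(f"coherence needs >= 2 windows, got {n_windows}")
    denom = np.sqrt(sxx * syy)
    icoh = np.zeros_like(denom)
    ok = denom > 0
    if not np.all(ok):
        warnings.warn("zero-power bins encountered; their coherence is set to 0")
    icoh[ok] = np.abs(np.imag(sxy[ok] / denom[ok]))
    return CoherenceSpectrum(freqs_hz=f, icoh=np.clip(icoh, 0.0, 1.0))


def band_mean_coherence(cs: CoherenceSpectrum, band: BandDefinition) -> float:
    """Mean |Im C| over the band's inclusive integer bins."""
    ps = PowerSpectrum(freqs_hz=cs.freqs_hz, power=cs.icoh)
    return band_mean(ps, band)
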