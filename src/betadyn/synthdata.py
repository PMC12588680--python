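"""Synthetic recordings and cohort endpoint tables with known ground truth.

Recordings are built from three controllable ingredients:

* a 1/f^a background (white noise shaped in the frequency domain, unit SD),
  plus an optional 50 Hz mains sinusoid;
* band-limited beta bursts: Poisson event counts in time, gamma-distributed
  durations, an integer carrier frequency inside the sub-band and a
  cosine-tapered (Tukey) amplitude envelope expressed in background-SD units;
* an optional shared beta-band source mixed into both channels with a sample
  delay at STN, which produces genuinely *imaginary* (lagged) coherence.

Cohorts add group-by-week trajectory multipliers on the burst/power parameters
and draw behaviour / histology endpoints from an explicit linear-Gaussian path
model, so parameter-recovery tests have a closed-form truth.

All randomness flows from a single root seed; each subject gets a
deterministically derived child stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .sigio import Recording

__all__ = [
    "BurstEvent",
    "SynthRecordingConfig",
    "GroupSpec",
    "CohortConfig",
    "TrueParameters",
    "simulate_recording",
    "simulate_endpoint_table",
    "simulate_cohort",
    "endpoint_units",
]

CHANNELS = ("MCx", "STN")


@dataclass(frozen=True)
class BurstEvent:
    """Ground-truth injected burst."""

    onset_s: float
    duration_s: float
    center_freq_hz: float
    amplitude: float  # envelope gain relative to background SD

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if not 13 <= self.center_freq_hz <= 30:
            raise ValueError("center_freq_hz must lie in the beta band [13, 30]")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SynthRecordingConfig:
    fs_hz: float = 256.0
    duration_s: float = 120.0
    one_over_f_exponent: float = 1.0
    line_freq_hz: float = 50.0
    line_gain: float = 0.3
    #: expected events/min in each sub-band (low beta 13-20, high beta 21-30)
    burst_rate_per_min: float = 8.0
    burst_bands: tuple[tuple[int, int], ...] = ((13, 20), (21, 30))
    burst_duration_shape: float = 3.0
    burst_duration_scale: float = 0.08  # gamma mean 0.24 s
    burst_amplitude_mean: float = 2.5
    burst_amplitude_sd: float = 0.5
    burst_min_gap_s: float = 0.2
    burst_taper: float = 0.5  # Tukey alpha: fraction of the event under cosine ramps
    coupling_gain: float = 0.0
    coupling_lag_ms: float = 10.0
    coupling_band: tuple[float, float] = (13.0, 30.0)
    seed: int = 0
    #: deterministic events injected verbatim, bypassing the Poisson process
    forced_events: Mapping[str, Sequence[BurstEvent]] | None = None

    def __post_init__(self) -> None:
        if self.duration_s < 1.0:
            raise ValueError("duration_s must be at least 1 s (one analysis window)")
        if not 0.0 <= self.coupling_gain <= 1.0:
            raise ValueError("coupling_gain must lie in [0, 1]")
        for name in ("burst_rate_per_min", "burst_duration_shape",
                     "burst_duration_scale", "burst_amplitude_mean", "line_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _background(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """White noise shaped to 1/f^exponent in the frequency domain, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    # leave frequencies below 0.5 Hz flat: the hardware high-pass removes them
    # anyway and 1/f diverges at DC
    shape = np.maximum(f, 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _burst_waveform(event: BurstEvent, fs: float, taper: float,
                    phase: float) -> np.ndarray:
    n = max(int(round(event.duration_s * fs)), 2)
    t = np.arange(n) / fs
    env = sps.windows.tukey(n, alpha=taper)
    return event.amplitude * env * np.sin(2 * np.pi * event.center_freq_hz * t + phase)


def _draw_events(cfg: SynthRecordingConfig, rng: np.random.Generator,
                 existing: list[BurstEvent]) -> list[BurstEvent]:
    events = list(existing)
    for lo, hi in cfg.burst_bands:
        n_ev = rng.poisson(cfg.burst_rate_per_min * cfg.duration_s / 60.0)
        for _ in range(n_ev):
            dur = float(np.clip(
                rng.gamma(cfg.burst_duration_shape, cfg.burst_duration_scale), 0.10, 2.0))
            amp = float(max(rng.normal(cfg.burst_amplitude_mean, cfg.burst_amplitude_sd), 0.5))
            freq = float(rng.integers(lo, hi + 1))
            placed = None
            for _try in range(200):  # resample collisions
                onset = float(rng.uniform(0.0, max(cfg.duration_s - dur, 0.0)))
                cand = BurstEvent(onset, dur, freq, amp)
                gap = cfg.burst_min_gap_s
                if all(cand.end_s + gap <= e.onset_s or cand.onset_s >= e.end_s + gap
                       for e in events):
                    placed = cand
                    break
            if placed is not None:
                events.append(placed)
    return sorted(events, key=lambda e: e.onset_s)


def simulate_recording(
    cfg: SynthRecordingConfig,
) -> tuple[Recording, dict[str, list[BurstEvent]]]:
    """Render a two-channel (MCx, STN) recording plus its injected events.

    Identical config + seed gives bit-identical output. The returned event
    lists are the exact ground truth, per channel.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_hz
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs

    channels: dict[str, np.ndarray] = {}
    truth: dict[str, list[BurstEvent]] = {}
    for label in CHANNELS:
        x = _background(n, fs, cfg.one_over_f_exponent, rng)
        if cfg.line_gain > 0:
            x = x + cfg.line_gain * np.sin(
                2 * np.pi * cfg.line_freq_hz * t + rng.uniform(0, 2 * np.pi))
        forced = list((cfg.forced_events or {}).get(label, []))
        events = _draw_events(cfg, rng, forced) if cfg.burst_rate_per_min > 0 else sorted(
            forced, key=lambda e: e.onset_s)
        for ev in events:
            i0 = int(np.floor(ev.onset_s * fs))
            w = _burst_waveform(ev, fs, cfg.burst_taper, rng.uniform(0, 2 * np.pi))
            i1 = min(i0 + w.size, n)
            x[i0:i1] += w[: i1 - i0]
        channels[label] = x
        truth[label] = events

    if cfg.coupling_gain > 0:
        lo, hi = cfg.coupling_band
        b, a = sps.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
        src = sps.filtfilt(b, a, rng.standard_normal(n))
        src = src / src.std()
        lag = int(round(cfg.coupling_lag_ms * fs / 1000.0))
        lagged = np.zeros(n)
        if lag < n:
            lagged[lag:] = src[: n - lag] if lag > 0 else src
        channels["MCx"] = channels["MCx"] + cfg.coupling_gain * src
        channels["STN"] = channels["STN"] + cfg.coupling_gain * lagged

    rec = Recording(
        samples=np.vstack([channels[c] for c in CHANNELS]),
        fs_hz=fs,
        channel_labels=CHANNELS,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group with a week -> severity-multiplier trajectory."""

    label: str
    n_subjects: int
    trajectory: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"group {self.label}: n_subjects must be >= 1")
        if any(m < 0 for m in self.trajectory.values()):
            raise ValueError(f"group {self.label}: trajectory multipliers must be >= 0")


def _default_groups() -> tuple[GroupSpec, ...]:
    # Emulates an empty-vector control plus low/high-titre disease groups:
    # controls stay flat, the low group ramps late and mildly, the high group
    # ramps early and strongly.
    return (
        GroupSpec("EV", 6, {2: 1.0, 3: 1.0, 4: 1.0, 6: 1.0, 8: 1.0}),
        GroupSpec("A53T-low", 6, {2: 1.0, 3: 1.1, 4: 1.3, 6: 1.5, 8: 1.7}),
        GroupSpec("A53T-high", 6, {2: 1.4, 3: 1.8, 4: 2.2, 6: 2.6, 8: 3.0}),
    )


def _default_paths() -> dict[tuple[str, str], float]:
    # Latent beta burden (exogenous, trajectory-driven) propagates cortex ->
    # STN and from there to behaviour and the two degeneration endpoints.
    return {
        ("mcx_beta", "stn_beta"): 0.65,
        ("stn_beta", "behavior"): 0.7,
        ("stn_beta", "th_deficit"): 0.6,
        ("stn_beta", "od_deficit"): 0.55,
    }


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    weeks: tuple[int, ...] = (2, 3, 4, 6, 8)
    #: (from, to) -> coefficient of the generative linear path model (z scale)
    endpoint_path_coefficients: Mapping[tuple[str, str], float] = field(
        default_factory=_default_paths)
    #: residual SD per endogenous variable (scalar applies to all)
    noise_sd: float | Mapping[str, float] = 0.5
    recording: SynthRecordingConfig = field(default_factory=SynthRecordingConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ValueError("weeks must be strictly increasing")
        for g in self.groups:
            missing = [w for w in self.weeks if w not in g.trajectory]
            if missing:
                raise ValueError(f"group {g.label} lacks multipliers for weeks {missing}")


@dataclass(frozen=True)
class TrueParameters:
    """Everything the generator used, for recovery tests."""

    path_coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    trajectories: dict[str, dict[int, float]]
    seed: int


def _topo_order(variables: set[str], edges: Mapping[tuple[str, str], float]) -> list[str]:
    parents: dict[str, list[str]] = {v: [] for v in variables}
    for (src, dst) in edges:
        parents[dst].append(src)
    order: list[str] = []
    seen: set[str] = set()

    def visit(v: str, stack: tuple[str, ...] = ()) -> None:
        if v in stack:
            raise ValueError(f"path model contains a cycle through {v!r}")
        if v in seen:
            return
        for p in parents[v]:
            visit(p, stack + (v,))
        seen.add(v)
        order.append(v)

    for v in sorted(variables):
        visit(v)
    return order


def simulate_endpoint_table(
    cfg: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TrueParameters]:
    """Draw subject-week endpoint rows from the configured linear path model.

    Exogenous variables are N(mu, 1) where mu is the group-week trajectory
    multiplier centred on the cohort mean; endogenous variables are the linear
    combination of their parents plus N(0, noise_sd). This fast path carries
    the identical generative model used by :func:`simulate_cohort` and is what
    large-n parameter-recovery simulations should call.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    edges = dict(cfg.endpoint_path_coefficients)
    variables = {v for e in edges for v in e}
    order = _topo_order(variables, edges)
    endo = {dst for (_, dst) in edges}
    if isinstance(cfg.noise_sd, Mapping):
        noise = {v: float(cfg.noise_sd.get(v, 0.5)) for v in endo}
    else:
        noise = {v: float(cfg.noise_sd) for v in endo}

    all_mult = [g.trajectory[w] for g in cfg.groups for w in cfg.weeks]
    mu_center = float(np.mean(all_mult))

    rows = []
    for g in cfg.groups:
        for s in range(g.n_subjects):
            sid = f"{g.label}-{s + 1:02d}"
            for w in cfg.weeks:
                mu = g.trajectory[w] - mu_center
                vals: dict[str, float] = {}
                for v in order:
                    if v in endo:
                        pred = sum(c * vals[src] for (src, dst), c in edges.items() if dst == v)
                        vals[v] = pred + noise[v] * rng.standard_normal()
                    else:
                        vals[v] = mu + rng.standard_normal()
                rows.append({"subject": sid, "group": g.label, "week": w, **vals})
    df = pd.DataFrame(rows)
    truth = TrueParameters(
        path_coefficients=edges,
        noise_sd=noise,
        trajectories={g.label: dict(g.trajectory) for g in cfg.groups},
        seed=cfg.seed,
    )
    return df, truth


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[dict[tuple[str, int], tuple[Recording, dict[str, list[BurstEvent]]]],
           pd.DataFrame, TrueParameters]:
    """Render one recording per subject-week plus the endpoint table.

    Trajectory multipliers scale the burst rate and amplitude (and coupling
    gain, capped at 1) of each subject-week recording, so extracted features
    really do progress the way the endpoint table's latent variables say.
    """
    root = np.random.default_rng(cfg.seed)
    endpoint_df, truth = simulate_endpoint_table(cfg, np.random.default_rng(root.integers(2**31)))

    recordings: dict[tuple[str, int], tuple[Recording, dict[str, list[BurstEvent]]]] = {}
    for g in cfg.groups:
        for s in range(g.n_subjects):
            sid = f"{g.label}-{s + 1:02d}"
            child = int(root.integers(2**31))
            for k, w in enumerate(cfg.weeks):
                m = g.trajectory[w]
                # severity loads mostly on burst rate/duration; raw amplitude
                # moves mildly so bursts stay physiological (and below any
                # amplitude-based artifact screen)
                rc = replace(
                    cfg.recording,
                    burst_rate_per_min=cfg.recording.burst_rate_per_min * m,
                    burst_amplitude_mean=cfg.recording.burst_amplitude_mean
                    * (1.0 + 0.3 * (m - 1.0)),
                    burst_duration_scale=cfg.recording.burst_duration_scale
                    * (1.0 + 0.5 * (m - 1.0)),
                    coupling_gain=min(cfg.recording.coupling_gain * m, 1.0),
                    seed=child + k,
                )
                rec, events = simulate_recording(rc)
                rec.subject_id, rec.group_label, rec.week = sid, g.label, w
                recordings[(sid, w)] = (rec, events)
    return recordings, endpoint_df, truth


#: affine maps from the z-scale path-model variables to measurement units
ENDPOINT_SCALES: dict[str, tuple[str, float, float]] = {
    # model variable -> (output column, offset, scale)
    "behavior": ("cylinder_index", 50.0, 8.0),
    "th_deficit": ("th_count", 9000.0, -2000.0),
    "od_deficit": ("striatal_od", 100.0, -20.0),
}


def endpoint_units(table: pd.DataFrame) -> pd.DataFrame:
    """Map the default path-model variables onto measurement-unit endpoints.

    Cylinder index in percent around the symmetric 50%, TH+ cell counts around
    a healthy-control mean, striatal optical density as percent of the intact
    hemisphere. Unknown variables pass through unchanged.
    """
    out = table.copy()
    for var, (col, offset, scale) in ENDPOINT_SCALES.items():
        if var in out.columns:
            out[col] = offset + scale * out[var]
    if "cylinder_index" in out.columns:
        out["cylinder_index"] = out["cylinder_index"].clip(0.0, 100.0)
    if "th_count" in out.columns:
        out["th_count"] = out["th_count"].clip(lower=0.0)
    keep = ["subject", "group", "week"] + [c for _, (c, _, _) in ENDPOINT_SCALES.items()
                                           if c in out.columns]
    return out[keep]
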