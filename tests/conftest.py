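"""Shared fixtures: deterministic synthetic recordings and the injected-burst
recovery harness used by both the unit and acceptance suites."""

from __future__ import annotations

import numpy as np
import pytest

from betadyn.bursts import BurstConfig, band_envelope, detect_bursts, pooled_threshold, zscore
from betadyn.synthdata import BurstEvent, SynthRecordingConfig, simulate_recording

FS = 256.0
EPOCH_S = 30.0
N_EPOCHS = 3
#: duration mix for recovery fixtures: half the events exceed the 350 ms cutoff
RECOVERY_DURATIONS = (0.15, 0.2, 0.3, 0.4, 0.5, 0.6)


def make_recovery_events(seed: int, gap_s: float = 0.9) -> list[BurstEvent]:
    """Well-separated high-beta events tiling three 30-s epochs.

    The ~28% duty cycle keeps the pooled 75th-percentile threshold at the foot
    of the burst taper, where it cleanly separates events from background.
    """
    rng = np.random.default_rng(seed)
    events = []
    for ep in range(N_EPOCHS):
        t = ep * EPOCH_S + 1.0
        k = 0
        while True:
            dur = RECOVERY_DURATIONS[k % len(RECOVERY_DURATIONS)]
            if t + dur > (ep + 1) * EPOCH_S - 1.0:
                break
            events.append(BurstEvent(t, dur, float(rng.integers(21, 31)), 10.0))
            t += dur + gap_s
            k += 1
    return events


def run_burst_recovery(seed: int):
    """Simulate, run the detection pipeline, and match detections to truth.

    Returns (events, detected, matches) where matches maps each injected event
    to the list of detections overlapping it.
    """
    events = make_recovery_events(seed)
    cfg = SynthRecordingConfig(
        duration_s=N_EPOCHS * EPOCH_S, burst_rate_per_min=0.0, seed=seed,
        burst_taper=0.2, forced_events={"MCx": events})
    rec, _ = simulate_recording(cfg)
    bcfg = BurstConfig()
    x = rec.channel("MCx")
    envs = [
        band_envelope(zscore(x[int(ep * EPOCH_S * FS):int((ep + 1) * EPOCH_S * FS)]), FS, bcfg)
        for ep in range(N_EPOCHS)
    ]
    thr = pooled_threshold(envs, bcfg.threshold_quantile)
    detected = [
        b for ep, env in enumerate(envs)
        for b in detect_bursts(env, thr, FS, bcfg, t_offset_s=ep * EPOCH_S).bursts
    ]
    matches = {
        e: [d for d in detected if d.start_s < e.end_s and d.end_s > e.onset_s]
        for e in events
    }
    return events, detected, matches


@pytest.fixture(scope="session")
def clean_recording():
    """Burst-free, line-free 1/f background recording (120 s)."""
    rec, _ = simulate_recording(SynthRecordingConfig(
        duration_s=120.0, burst_rate_per_min=0.0, line_gain=0.0, seed=11))
    return rec


@pytest.fixture(scope="session")
def bursty_recording():
    """Default-parameter recording with its ground-truth event lists."""
    return simulate_recording(SynthRecordingConfig(duration_s=90.0, seed=21))
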