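import numpy as np
import pandas as pd
import pytest

from betadyn.connectivity import band_mean_coherence, imaginary_coherence
from betadyn.spectral import TOTAL_BETA, periodogram_hann
from betadyn.synthdata import (BurstEvent, CohortConfig, GroupSpec,
                               SynthRecordingConfig, endpoint_units,
                               simulate_cohort, simulate_endpoint_table,
                               simulate_recording)

FS = 256.0


class TestRecordingGenerator:
    def test_reproducibility_bit_identical(self):
        cfg = SynthRecordingConfig(duration_s=20.0, seed=42, coupling_gain=0.3)
        r1, t1 = simulate_recording(cfg)
        r2, t2 = simulate_recording(cfg)
        assert np.array_equal(r1.samples, r2.samples)
        assert t1 == t2

    def test_different_seeds_differ(self):
        r1, _ = simulate_recording(SynthRecordingConfig(duration_s=5.0, seed=1))
        r2, _ = simulate_recording(SynthRecordingConfig(duration_s=5.0, seed=2))
        assert not np.array_equal(r1.samples, r2.samples)

    def test_background_only_when_no_events_requested(self):
        rec, truth = simulate_recording(SynthRecordingConfig(
            duration_s=10.0, burst_rate_per_min=0.0, coupling_gain=0.0, seed=0))
        assert truth == {"MCx": [], "STN": []}
        assert rec.samples.shape == (2, 2560)

    def test_forced_event_found_by_detector(self):
        """A high-amplitude 400 ms event at 10 s is recovered by the burst
        pipeline as exactly one burst overlapping [10, 10.4] s."""
        from betadyn.bursts import band_envelope, detect_bursts, pooled_threshold, zscore

        ev = BurstEvent(10.0, 0.4, 25.0, 12.0)
        rec, truth = simulate_recording(SynthRecordingConfig(
            duration_s=30.0, burst_rate_per_min=0.0, seed=5, burst_taper=0.2,
            forced_events={"MCx": [ev]}))
        assert truth["MCx"] == [ev]
        env = band_envelope(zscore(rec.channel("MCx")), FS)
        thr = pooled_threshold([env], 0.99)  # sparse event: high quantile separates
        bs = detect_bursts(env, thr, FS)
        hits = [b for b in bs.bursts if b.start_s < 10.4 and b.end_s > 10.0]
        assert len(hits) == 1

    def test_event_counts_stable_across_seeds(self):
        """Across seeds the Poisson event machinery keeps the expected count:
        mean over 100 seeds within 2 SE of rate * duration."""
        rate, dur = 8.0, 60.0
        counts = [
            len(simulate_recording(SynthRecordingConfig(
                duration_s=dur, seed=s, burst_rate_per_min=rate))[1]["MCx"])
            for s in range(100)
        ]
        expect = 2 * rate * dur / 60.0  # two sub-bands
        se = np.std(counts, ddof=1) / 10.0
        assert abs(np.mean(counts) - expect) <= 2 * se + 0.5

    def test_events_respect_separation(self):
        _, truth = simulate_recording(SynthRecordingConfig(
            duration_s=60.0, seed=3, burst_rate_per_min=20.0))
        for evs in truth.values():
            for a, b in zip(evs, evs[1:]):
                assert b.onset_s >= a.end_s  # non-overlapping

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            SynthRecordingConfig(duration_s=0.5)

    def test_spectral_slope_contract(self):
        """Background periodogram slope over 5-45 Hz tracks the configured
        1/f exponent within +-0.3 (20 realizations)."""
        slopes = []
        for s in range(20):
            rec, _ = simulate_recording(SynthRecordingConfig(
                duration_s=30.0, seed=s, burst_rate_per_min=0.0, line_gain=0.0,
                one_over_f_exponent=1.2))
            ps = periodogram_hann(rec.channel("MCx"), FS)
            m = (ps.freqs_hz >= 5) & (ps.freqs_hz <= 45)
            slopes.append(-np.polyfit(np.log(ps.freqs_hz[m]), np.log(ps.power[m]), 1)[0])
        assert abs(np.mean(slopes) - 1.2) < 0.3

    def test_coupling_produces_imaginary_coherence(self):
        """Lagged shared source lifts band-mean icoh above the zero-coupling
        null's 95th percentile."""
        nulls, coupled = [], []
        for s in range(12):
            r0, _ = simulate_recording(SynthRecordingConfig(
                duration_s=60.0, seed=s, coupling_gain=0.0, burst_rate_per_min=0.0))
            r1, _ = simulate_recording(SynthRecordingConfig(
                duration_s=60.0, seed=s, coupling_gain=0.4, coupling_lag_ms=15.0,
                burst_rate_per_min=0.0))
            nulls.append(band_mean_coherence(imaginary_coherence(
                r0.channel("MCx"), r0.channel("STN"), FS), TOTAL_BETA))
            coupled.append(band_mean_coherence(imaginary_coherence(
                r1.channel("MCx"), r1.channel("STN"), FS), TOTAL_BETA))
        assert min(coupled) > np.percentile(nulls, 95)


class TestCohortGenerator:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("g", 0, {2: 1.0})
        with pytest.raises(ValueError):
            CohortConfig(weeks=(4, 2))
        with pytest.raises(ValueError):
            GroupSpec("g", 3, {2: -0.5})

    def test_null_path_model_gives_null_correlations(self):
        cfg = CohortConfig(
            groups=(GroupSpec("g", 200, {1: 1.0}),), weeks=(1,),
            endpoint_path_coefficients={("mcx_beta", "stn_beta"): 0.0,
                                        ("stn_beta", "behavior"): 0.0},
            noise_sd=1.0, seed=0)
        df, _ = simulate_endpoint_table(cfg)
        n = len(df)
        r = np.corrcoef(df["stn_beta"], df["behavior"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(n)

    def test_ols_recovers_generative_coefficient(self):
        cfg = CohortConfig(
            groups=(GroupSpec("g", 200, {1: 1.0}),), weeks=(1,),
            endpoint_path_coefficients={("beta_power", "behavior"): 0.7},
            noise_sd=0.5, seed=1)
        df, truth = simulate_endpoint_table(cfg)
        b = np.polyfit(df["beta_power"], df["behavior"], 1)[0]
        assert b == pytest.approx(truth.path_coefficients[("beta_power", "behavior")],
                                  abs=0.1)

    def test_cohort_shapes_and_determinism(self):
        cfg = CohortConfig(
            groups=(GroupSpec("a", 2, {2: 1.0, 8: 1.0}),
                    GroupSpec("b", 2, {2: 1.0, 8: 2.0})),
            weeks=(2, 8),
            recording=SynthRecordingConfig(duration_s=2.0), seed=9)
        recs, df, truth = simulate_cohort(cfg)
        assert len(recs) == 4 * 2
        assert len(df) == 4 * 2
        recs2, df2, _ = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(df, df2)
        k = ("a-01", 2)
        assert np.array_equal(recs[k][0].samples, recs2[k][0].samples)

    def test_progressive_group_long_bursts_increase(self):
        """A rising trajectory yields higher detected long-burst probability at
        the last week than the first, in the group mean."""
        from betadyn.pipeline import extract_features

        cfg = CohortConfig(
            groups=(GroupSpec("high", 4, {2: 1.0, 8: 3.0}),),
            weeks=(2, 8),
            recording=SynthRecordingConfig(duration_s=120.0, seed=0),
            seed=13)
        recs, _, _ = simulate_cohort(cfg)
        table = extract_features({(r.subject_id, r.group_label, r.week): r
                                  for r, _ in recs.values()})
        m = table.groupby("week")["stn_high_beta_burst_long_burst_prob"].mean()
        assert m[8] > m[2]

    def test_endpoint_units_mapping(self):
        df = pd.DataFrame({"subject": ["a"], "group": ["g"], "week": [2],
                           "behavior": [0.0], "th_deficit": [1.0], "od_deficit": [0.0]})
        out = endpoint_units(df)
        assert out.loc[0, "cylinder_index"] == 50.0
        assert out.loc[0, "th_count"] == 7000.0
        assert out.loc[0, "striatal_od"] == 100.0
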