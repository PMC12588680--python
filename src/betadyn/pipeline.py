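"""Orchestration: simulate -> epoch -> features -> statistics -> path models.

The feature table has one row per subject-week and a fixed column registry:
normalized band powers and burst statistics per region (MCx, STN), MCx-STN
imaginary-coherence band means, and the behaviour/histology endpoints. Burst
thresholds are pooled region-wise over the *entire* input set before any
per-subject detection, mirroring the common-threshold rule.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bursts import (BurstConfig, band_envelope, burst_stats, detect_bursts,
                     pooled_threshold, zscore)
from .connectivity import band_mean_coherence, imaginary_coherence
from .groupstats import compare_groups, correlate
from .semfit import (BehaviorDegenerationModel, CompositeScoreModel, PathModel,
                     cumulative_features)
from .sigio import EpochSet, Recording, select_epochs, write_recording
from .spectral import (HIGH_BETA, LOW_BETA, TOTAL_BETA, band_mean,
                       normalize_spectrum, periodogram_hann)
from .synthdata import CohortConfig, endpoint_units, simulate_cohort

log = logging.getLogger("betadyn")

__all__ = ["RunConfig", "FEATURE_COLUMNS", "extract_features", "run_all",
           "RAT_MODEL_1", "RAT_MODEL_2", "HUMAN_MODEL_1", "HUMAN_MODEL_2"]

_REGIONS = {"mcx": "MCx", "stn": "STN"}
_POWER_BANDS = {"total_beta": TOTAL_BETA, "high_beta": HIGH_BETA, "low_beta": LOW_BETA}
_BURST_BANDS = {"high_beta": HIGH_BETA, "low_beta": LOW_BETA}

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"{r}_{b}_power" for r in _REGIONS for b in _POWER_BANDS]
    + [f"coh_{b}" for b in _POWER_BANDS]
    + [f"{r}_{b}_burst_{s}" for r in _REGIONS for b in _BURST_BANDS
       for s in ("amplitude", "rate", "long_burst_prob")]
)

ENDPOINT_COLUMNS = ("cylinder_index", "th_count", "striatal_od")

# Model 1: high-beta power and burst amplitude, cortex as input and STN as
# mediator, predicting behaviour and the two degeneration endpoints.
RAT_MODEL_1 = """
mcx_high_beta_power -> stn_high_beta_power
mcx_high_beta_burst_amplitude -> stn_high_beta_burst_amplitude
stn_high_beta_power -> cylinder_index
stn_high_beta_burst_amplitude -> cylinder_index
stn_high_beta_power -> th_count
stn_high_beta_burst_amplitude -> th_count
stn_high_beta_power -> striatal_od
stn_high_beta_burst_amplitude -> striatal_od
"""

# Model 2: low-beta power from both regions as input, striatal optical
# density as the mediator.
RAT_MODEL_2 = """
mcx_low_beta_power -> striatal_od
stn_low_beta_power -> striatal_od
striatal_od -> cylinder_index
striatal_od -> th_count
"""

HUMAN_MODEL_1 = """
mcx_high_beta_power -> stn_high_beta_power
mcx_high_beta_burst_amplitude -> stn_high_beta_burst_amplitude
stn_high_beta_power -> updrs_iii_med_off
stn_high_beta_burst_amplitude -> updrs_iii_med_off
"""

HUMAN_MODEL_2 = """
mcx_low_beta_power -> striatal_binding
stn_low_beta_power -> striatal_binding
striatal_binding -> updrs_iii_med_off
"""


@dataclass
class RunConfig:
    outdir: str
    seed: int | None = None
    mode: str = "rat"  # "rat" | "human-features"
    feature_csv: str | None = None  # input table for human-features mode
    n_subjects: int = 4
    weeks: tuple[int, ...] = (2, 8)
    duration_s: float = 120.0
    n_epochs: int = 3
    epoch_s: float = 30.0
    artifact_k: float = 6.0
    threshold_quantile: float = 0.75
    write_signals: bool = True
    sem_models: Mapping[str, str] = field(default_factory=dict)  # name -> model text

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic step")
        if self.mode not in ("rat", "human-features"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "human-features" and not self.feature_csv:
            raise ValueError("human-features mode requires feature_csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "weeks" in raw:
            raw["weeks"] = tuple(raw["weeks"])
        return cls(**raw)


def _epoch_signals(rec: Recording, epochs: EpochSet) -> dict[str, list[np.ndarray]]:
    """Per-channel list of z-scored epoch segments."""
    fs = rec.fs_hz
    out: dict[str, list[np.ndarray]] = {}
    for lab in rec.channel_labels:
        ch = rec.channel(lab)
        segs = []
        for s, e in epochs.epochs:
            i0, i1 = int(np.floor(s * fs)), int(np.floor(e * fs))
            segs.append(zscore(ch[i0:i1]))
        out[lab] = segs
    return out


def extract_features(
    recordings: Mapping[tuple[str, str, int], Recording] | Sequence[Recording],
    burst_cfg: BurstConfig | None = None,
    n_epochs: int = 3,
    epoch_s: float = 30.0,
    artifact_k: float = 6.0,
    threshold_quantile: float = 0.75,
) -> pd.DataFrame:
    """Longitudinal feature table from a set of recordings.

    Two passes: the first selects epochs and accumulates band envelopes so the
    burst threshold can be pooled per region over the full input set; the
    second computes spectra, coherence and burst statistics per recording.
    Deterministic given inputs. A recording missing a region is flagged in the
    ``flags`` column rather than dropped.
    """
    if not isinstance(recordings, Mapping):
        recordings = {(r.subject_id, r.group_label, r.week): r for r in recordings}
    base_cfg = burst_cfg or BurstConfig(threshold_quantile=threshold_quantile)

    # pass 1: epochs + envelope pools
    prepared: dict[tuple, tuple[Recording, EpochSet, dict]] = {}
    pools: dict[tuple[str, str], list[np.ndarray]] = {}
    for key, rec in sorted(recordings.items()):
        epochs = select_epochs(rec, n_epochs=n_epochs, epoch_s=epoch_s, artifact_k=artifact_k)
        zsegs = _epoch_signals(rec, epochs)
        envs: dict[tuple[str, str], list[np.ndarray]] = {}
        for rkey, rlabel in _REGIONS.items():
            if rlabel not in rec.channel_labels:
                continue
            for bkey, band in _BURST_BANDS.items():
                cfg_b = dataclasses.replace(base_cfg, band=band)
                e = [band_envelope(seg, rec.fs_hz, cfg_b) for seg in zsegs[rlabel]]
                envs[(rkey, bkey)] = e
                pools.setdefault((rkey, bkey), []).extend(e)
        prepared[key] = (rec, epochs, envs)

    thresholds = {
        k: pooled_threshold(v, quantile=base_cfg.threshold_quantile)
        for k, v in pools.items()
    }

    # pass 2: per-recording features
    rows = []
    for (sid, grp, week), (rec, epochs, envs) in prepared.items():
        row: dict = {"subject": sid, "group": grp, "week": week, "flags": ""}
        flags = []
        for rkey, rlabel in _REGIONS.items():
            if rlabel not in rec.channel_labels:
                flags.append(f"missing:{rlabel}")
                for b in _POWER_BANDS:
                    row[f"{rkey}_{b}_power"] = np.nan
                for b in _BURST_BANDS:
                    for s in ("amplitude", "rate", "long_burst_prob"):
                        row[f"{rkey}_{b}_burst_{s}"] = np.nan
                continue
            ps = normalize_spectrum(
                periodogram_hann(rec.channel(rlabel), rec.fs_hz, epochs.epochs))
            for bkey, band in _POWER_BANDS.items():
                row[f"{rkey}_{bkey}_power"] = band_mean(ps, band)
            for bkey, band in _BURST_BANDS.items():
                cfg_b = dataclasses.replace(base_cfg, band=band)
                thr = thresholds[(rkey, bkey)]
                sets = [detect_bursts(env, thr, rec.fs_hz, cfg_b,
                                      t_offset_s=epochs.epochs[i][0])
                        for i, env in enumerate(envs[(rkey, bkey)])]
                st = burst_stats(sets, epochs.total_time_s, cfg_b.long_duration_s)
                row[f"{rkey}_{bkey}_burst_amplitude"] = st.amplitude
                row[f"{rkey}_{bkey}_burst_rate"] = st.rate
                row[f"{rkey}_{bkey}_burst_long_burst_prob"] = st.long_burst_prob
        if all(l in rec.channel_labels for l in ("MCx", "STN")):
            cs = imaginary_coherence(rec.channel("MCx"), rec.channel("STN"),
                                     rec.fs_hz, epochs.epochs)
            for bkey, band in _POWER_BANDS.items():
                row[f"coh_{bkey}"] = band_mean_coherence(cs, band)
        else:
            for bkey in _POWER_BANDS:
                row[f"coh_{bkey}"] = np.nan
        row["flags"] = ";".join(flags)
        rows.append(row)
    cols = ["subject", "group", "week", *FEATURE_COLUMNS, "flags"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# Full run

def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))


def _neurodegeneration_target(table: pd.DataFrame, control_group: str = "EV") -> pd.Series:
    """Mean of min-max-normalized TH-cell loss and striatal-OD loss.

    Loss fractions are 1 - value / control-group mean; each is min-max scaled
    over the cohort before averaging so both endpoints weigh equally.
    """
    per_subject = table.groupby("subject").agg(
        th=("th_count", "mean"), od=("striatal_od", "mean"),
        group=("group", "first"))
    ref_th = per_subject.loc[per_subject["group"] == control_group, "th"].mean()
    ref_od = per_subject.loc[per_subject["group"] == control_group, "od"].mean()
    loss_th = 1.0 - per_subject["th"] / ref_th
    loss_od = 1.0 - per_subject["od"] / ref_od

    def mm(x):
        rng = x.max() - x.min()
        return (x - x.min()) / rng if rng > 0 else x * 0.0

    return (mm(loss_th) + mm(loss_od)) / 2.0


def _stage(outdir: Path, name: str):
    """Context guard: on failure persist a marker naming the failed stage."""
    import contextlib

    @contextlib.contextmanager
    def guard():
        try:
            yield
        except Exception as exc:
            failed = outdir / "failed"
            failed.mkdir(parents=True, exist_ok=True)
            (failed / f"{name}.txt").write_text(f"{type(exc).__name__}: {exc}\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    return guard()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a dict of output paths and summary numbers."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    report: dict = {"version": __version__, "seed": cfg.seed, "mode": cfg.mode}
    log.info("betadyn %s run, mode=%s seed=%s", __version__, cfg.mode, cfg.seed)

    if cfg.mode == "rat":
        with _stage(outdir, "simulate"):
            from .synthdata import GroupSpec, SynthRecordingConfig
            traj = {
                "EV": {w: 1.0 for w in cfg.weeks},
                "A53T-low": {w: 1.0 + 0.1 * i for i, w in enumerate(cfg.weeks)},
                "A53T-high": {w: 1.4 + 0.4 * i for i, w in enumerate(cfg.weeks)},
            }
            cohort = CohortConfig(
                groups=tuple(GroupSpec(g, cfg.n_subjects, t) for g, t in traj.items()),
                weeks=tuple(cfg.weeks),
                recording=SynthRecordingConfig(
                    duration_s=cfg.duration_s, coupling_gain=0.2, seed=cfg.seed),
                seed=cfg.seed,
            )
            recordings, endpoints_z, truth = simulate_cohort(cohort)
            endpoints = endpoint_units(endpoints_z)
            endpoints.to_csv(outdir / "endpoints.csv", index=False)
            if cfg.write_signals:
                sigdir = outdir / "signals"
                sigdir.mkdir(exist_ok=True)
                for (sid, week), (rec, events) in recordings.items():
                    write_recording(rec, sigdir / f"{sid}_w{week}.edf")
                    pd.DataFrame(
                        [{"channel": ch, "onset_s": e.onset_s, "duration_s": e.duration_s,
                          "center_freq_hz": e.center_freq_hz, "amplitude": e.amplitude}
                         for ch, evs in events.items() for e in evs]
                    ).to_csv(sigdir / f"{sid}_w{week}_events.csv", index=False)

        with _stage(outdir, "features"):
            table = extract_features(
                {(r.subject_id, r.group_label, r.week): r
                 for r, _ in recordings.values()},
                n_epochs=cfg.n_epochs, epoch_s=cfg.epoch_s,
                artifact_k=cfg.artifact_k, threshold_quantile=cfg.threshold_quantile)
            table = table.merge(endpoints, on=["subject", "group", "week"], how="left")
            table.to_csv(outdir / "features.csv", index=False)
            report["features_csv"] = str(outdir / "features.csv")
    else:
        with _stage(outdir, "features"):
            table = pd.read_csv(cfg.feature_csv)
            report["features_csv"] = str(cfg.feature_csv)

    with _stage(outdir, "stats"):
        stats_out: dict = {"group_comparisons": {}, "correlations": {}}
        if cfg.mode == "rat":
            glabels = sorted(table["group"].unique())
            final_week = table["week"].max()
            for col in list(FEATURE_COLUMNS) + ["cylinder_index"]:
                sub = table[table["week"] == final_week]
                grps = [sub.loc[sub["group"] == g, col].dropna().to_numpy()
                        for g in glabels]
                if any(g.size < 3 for g in grps):
                    continue
                tr = compare_groups(grps, glabels)
                stats_out["group_comparisons"][col] = {
                    "test": tr.test_name, "statistic": tr.statistic,
                    "label": tr.statistic_label(), "p": tr.p_value,
                    "posthoc": [list(t) for t in tr.posthoc]}
            sub = table[table["week"] == final_week].dropna(subset=["cylinder_index"])
            for col in FEATURE_COLUMNS:
                v = sub[[col, "cylinder_index"]].dropna()
                if len(v) >= 4 and v[col].std() > 0:
                    cr = correlate(v[col].to_numpy(), v["cylinder_index"].to_numpy())
                    stats_out["correlations"][col] = {
                        "method": cr.method, "r": cr.r, "p": cr.p_value, "n": cr.n}
        _write_json(stats_out, outdir / "stats.json")
        report["stats_json"] = str(outdir / "stats.json")

    with _stage(outdir, "sem"):
        models = dict(cfg.sem_models)
        if not models:
            if cfg.mode == "rat":
                models = {"model1_high_beta": RAT_MODEL_1, "model2_low_beta": RAT_MODEL_2}
            else:
                models = {"model1_high_beta": HUMAN_MODEL_1, "model2_low_beta": HUMAN_MODEL_2}
        sem_out = {}
        for name, text in models.items():
            pm = PathModel.from_text(text)
            have = [v for v in pm.variables if v in table.columns]
            if len(have) < len(pm.variables):
                sem_out[name] = {"skipped": f"missing columns "
                                 f"{sorted(set(pm.variables) - set(have))}"}
                continue
            fit = pm.fit(table)
            sem_out[name] = fit.to_dict()
        _write_json(sem_out, outdir / "sem.json")
        report["sem_json"] = str(outdir / "sem.json")

    if cfg.mode == "rat":
        with _stage(outdir, "composite"):
            menu = [c for c in FEATURE_COLUMNS if not c.startswith("coh_")]
            menu += ["coh_total_beta", "coh_high_beta"]
            cum = cumulative_features(
                table.dropna(subset=list(FEATURE_COLUMNS)), menu)
            final = cum[cum["week"] == cum["week"].max()].set_index("subject")
            target = _neurodegeneration_target(table)
            comp_out = {}
            for g in sorted(final["group"].unique()):
                sel = final[final["group"] == g]
                y = target.loc[sel.index]
                model = CompositeScoreModel(sel[menu], y, groups=None)
                comp_out[g] = model.fit().to_dict()
            _write_json(comp_out, outdir / "composite.json")
            report["composite_json"] = str(outdir / "composite.json")

        with _stage(outdir, "curves"):
            per_subj = table.groupby("subject").agg(
                group=("group", "first"),
                beh=("cylinder_index", lambda s: s.iloc[-1]))
            deg = 100.0 * _neurodegeneration_target(table)
            merged = per_subj.join(deg.rename("deg"))
            two = np.where(merged["group"] == "EV", "EV", "A53T")
            try:
                curves = BehaviorDegenerationModel(
                    merged["deg"], np.abs(merged["beh"] - 50.0), two).fit()
                _write_json({g: {"midpoint_pct": c.midpoint, "slope": c.slope, "n": c.n}
                             for g, c in curves.items()}, outdir / "curves.json")
                report["curves_json"] = str(outdir / "curves.json")
            except ValueError as exc:
                _write_json({"skipped": str(exc)}, outdir / "curves.json")

    (outdir / "run.log").write_text(
        f"betadyn {__version__}\nseed {cfg.seed}\nmode {cfg.mode}\n")
    return report
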