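"""End-to-end orchestration: generate -> track -> chirps -> recovery -> stats.

A run takes a single :class:`RunConfig` (all stage configurations plus a
mandatory seed), executes every stage on the synthetic experiment (or on
user-supplied recordings via the CLI), and produces a :class:`RunReport`
mirroring the assay's summary tables: per-trial baseline medians and cv,
maximum frequency drops, chirp counts before/after anesthesia, pooled
recovery-model parameters per concentration, exact sign tests, the
split-plot mixed-model fit, and sliding-window recovery times.  Identical
config + seed reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eod_io
from .chirps import ChirpDetectConfig, chirp_rate_summary, detect_chirps
from .recovery import (amplitude_envelope, detect_amplitude_collapse,
                       fit_recovery_model, normalize_frequency)
from .stats import (fit_mixed_model, joint_concentration_test,
                    make_mixed_model_frame, recovery_time, sign_test_exact)
from .synthetic import GeneratorConfig, Phases, generate_experiment
from .tracking import (TrackConfig, adjust_temperature, baseline_dominant_frequency,
                       coefficient_of_variation, median_frequency_series,
                       track_frequency)

log = logging.getLogger("eodassay")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one analysis run."""

    seed: int
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    chirp: ChirpDetectConfig = field(default_factory=ChirpDetectConfig)
    freq_after_window_s: float = 900.0  # 15 min from treatment onset
    chirp_pre_window_s: float = 1800.0
    chirp_post_window_s: float = 1800.0
    alpha: float = 0.01
    recovery_window_len: int = 15
    write_tracks: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["recovery_params"] = {
            str(k): dataclasses.asdict(v)
            for k, v in self.generator.recovery_params.items()}
        d["generator"]["chirp_post_extra_per_min"] = {
            str(k): v for k, v in self.generator.chirp_post_extra_per_min.items()}
        return d


def run_config_from_dict(d: dict) -> RunConfig:
    from .recovery import RecoveryModelParams

    d = dict(d)
    gen = dict(d.pop("generator", {}))
    if "phases" in gen:
        gen["phases"] = Phases(**gen["phases"])
    if "recovery_params" in gen:
        gen["recovery_params"] = {float(k): RecoveryModelParams(**v)
                                  for k, v in gen["recovery_params"].items()}
    if "chirp_post_extra_per_min" in gen:
        gen["chirp_post_extra_per_min"] = {
            float(k): float(v) for k, v in gen["chirp_post_extra_per_min"].items()}
    for tup in ("f0_range_hz", "concentrations", "harmonics", "chirp_df_range_hz",
                "chirp_alpha_range_per_s", "chirp_amp_dip_range"):
        if tup in gen:
            gen[tup] = tuple(gen[tup])
    track = dict(d.pop("track", {}))
    for tup in ("search_band", "filter_band", "baseline_band_hz"):
        if tup in track:
            track[tup] = tuple(track[tup])
    chirp = dict(d.pop("chirp", {}))
    for tup in ("band_factors", "alpha_bounds"):
        if tup in chirp:
            chirp[tup] = tuple(chirp[tup])
    return RunConfig(generator=GeneratorConfig(**gen), track=TrackConfig(**track),
                     chirp=ChirpDetectConfig(**chirp), **d)


def load_run_config(path) -> RunConfig:
    return run_config_from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """All summary tables of one run; every number traces to a CSV artifact."""

    per_trial: pd.DataFrame
    recovery_params: pd.DataFrame
    sign_tests: pd.DataFrame
    mixed_model: dict
    recovery_times: dict[float, dict]
    config: RunConfig

    def to_json(self) -> str:
        payload = {
            "per_trial": self.per_trial.round(10).to_dict(orient="records"),
            "recovery_params": self.recovery_params.round(10).to_dict(orient="records"),
            "sign_tests": self.sign_tests.round(10).to_dict(orient="records"),
            "mixed_model": self.mixed_model,
            "recovery_times": {str(k): v for k, v in self.recovery_times.items()},
            "config": self.config.to_dict(),
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=float)


def _analyze_trial(rec, run_config: RunConfig):
    """Track, median series, temperature adjustment, drops and chirps of one trial."""
    ph = rec.metadata.phases
    baseline = rec.phase_slice(0.0, ph.treatment_onset_s)
    f_d0 = baseline_dominant_frequency(baseline, rec.rate_hz,
                                       band_hz=run_config.track.baseline_band_hz)
    track = track_frequency(rec.samples, rec.rate_hz, f_d0, run_config.track)
    series = median_frequency_series(track)
    temps = np.interp(series.times_s, rec.metadata.temperature_times_s,
                      rec.metadata.temperature_c)
    medians = adjust_temperature(series.medians_hz, temps)

    before = medians[series.times_s < ph.treatment_onset_s]
    after_sel = ((series.times_s >= ph.treatment_onset_s)
                 & (series.times_s < ph.treatment_onset_s + run_config.freq_after_window_s))
    baseline_median = float(np.median(before))
    cv = coefficient_of_variation(before)
    after_median = float(np.median(medians[after_sel])) if np.any(after_sel) else np.nan

    post_sel = series.times_s >= ph.treatment_onset_s
    drop_hz = baseline_median - float(np.min(medians[post_sel]))
    norm_min = float(np.min(medians[post_sel])) / baseline_median

    events = detect_chirps(rec.samples, rec.rate_hz, f_d0, run_config.chirp,
                           start_s=rec.start_s)
    summary = chirp_rate_summary(
        events, ph.treatment_onset_s, ph.return_s, rec.duration_s,
        pre_window_s=min(run_config.chirp_pre_window_s, ph.baseline_s),
        post_window_s=min(run_config.chirp_post_window_s, ph.post_s))

    env = amplitude_envelope(rec.samples, rec.rate_hz)
    env_base = env.baseline_median((0.0, ph.treatment_onset_s))
    collapses = detect_amplitude_collapse(env, env_base)

    normalized = normalize_frequency(series.times_s, medians,
                                     (0.0, ph.treatment_onset_s), ph.return_s)
    return {
        "f_d0": f_d0,
        "track": track,
        "series": series,
        "medians_adj": medians,
        "baseline_median_hz": baseline_median,
        "cv_percent": cv,
        "after_median_hz": after_median,
        "freq_change_hz": after_median - baseline_median,
        "max_drop_hz": drop_hz,
        "normalized_min": norm_min,
        "events": events,
        "chirps_pre": summary.counts["pre"],
        "chirps_post": summary.counts["post"],
        "collapses": collapses,
        "normalized": normalized,
    }


def run_full_analysis(config: RunConfig, outdir=None) -> RunReport:
    """Execute every stage of the assay on a synthetic experiment."""
    t_start = time.time()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    log.info("stage=simulate seed=%d n_fish=%d", config.seed, config.generator.n_fish)
    dataset = generate_experiment(config.generator, config.seed)

    trial_rows = []
    per_trial_results = {}
    for (fid, conc) in sorted(dataset.trials):
        t0 = time.time()
        rec = dataset.realize(fid, conc)
        try:
            res = _analyze_trial(rec, config)
        except Exception as exc:
            raise RuntimeError(f"stage=analyze trial={fid}@{conc} failed: {exc}") from exc
        per_trial_results[(fid, conc)] = res
        trial_rows.append({
            "fish": fid, "concentration_ul_per_l": conc,
            "f0_true_hz": dataset.f0_by_fish[fid], "f_d0_hz": res["f_d0"],
            "baseline_median_hz": res["baseline_median_hz"],
            "cv_percent": res["cv_percent"],
            "freq_change_hz": res["freq_change_hz"],
            "max_drop_hz": res["max_drop_hz"],
            "normalized_min": res["normalized_min"],
            "chirps_pre": res["chirps_pre"], "chirps_post": res["chirps_post"],
            "chirp_increase": res["chirps_post"] - res["chirps_pre"],
            "n_true_chirps": len(dataset.trials[(fid, conc)].chirps),
            "n_amp_collapses": len(res["collapses"]),
            "collapse_onset_s": (res["collapses"][0].onset_s
                                 if res["collapses"] else np.nan),
        })
        log.info("stage=analyze trial=%s@%g dt=%.1fs", fid, conc, time.time() - t0)
        if outdir is not None:
            stem = f"{fid}_{conc:g}"
            eod_io.median_series_to_frame(res["series"]).to_csv(
                outdir / f"medians_{stem}.csv", index=False)
            eod_io.events_to_frame(res["events"]).to_csv(
                outdir / f"chirps_{stem}.csv", index=False)
            if config.write_tracks:
                eod_io.track_to_frame(res["track"]).to_csv(
                    outdir / f"track_{stem}.csv", index=False)
    per_trial = pd.DataFrame(trial_rows)

    # pooled recovery-model fits per concentration
    fit_rows = []
    concentrations = sorted(c for c in config.generator.concentrations if c > 0)
    for conc in concentrations:
        t_all, y_all = [], []
        for fid in dataset.fish_ids:
            norm = per_trial_results[(fid, conc)]["normalized"].post
            t_all.append(norm.t_min)
            y_all.append(norm.values)
        try:
            fit = fit_recovery_model(np.concatenate(t_all), np.concatenate(y_all))
            fit_rows.append({"concentration_ul_per_l": conc, "a": fit.params.a,
                             "b_min": fit.params.b, "c": fit.params.c,
                             "d_per_min": fit.params.d, "rmse": fit.rmse,
                             "n_points": fit.n_points})
        except (RuntimeError, ValueError) as exc:
            log.warning("stage=recovery conc=%g failed: %s", conc, exc)
            fit_rows.append({"concentration_ul_per_l": conc, "a": np.nan,
                             "b_min": np.nan, "c": np.nan, "d_per_min": np.nan,
                             "rmse": np.nan, "n_points": 0})
    recovery_params = pd.DataFrame(fit_rows)

    sign_rows = []

    def _sign_row(table: str, label: str, diffs):
        diffs = np.asarray(diffs, dtype=float)
        try:
            res = sign_test_exact(diffs)
            sign_rows.append({"table": table, "comparison": label, "n": res.n,
                              "n_positive": res.n_positive, "n_negative": res.n_negative,
                              "p_value": res.p_value,
                              "median": float(np.median(diffs))})
        except ValueError:
            sign_rows.append({"table": table, "comparison": label, "n": 0,
                              "n_positive": 0, "n_negative": 0,
                              "p_value": np.nan, "median": float(np.median(diffs))})

    def _col(conc, name):
        sub = per_trial[per_trial["concentration_ul_per_l"] == conc]
        return sub.sort_values("fish")[name].to_numpy(float)

    all_concs = sorted(config.generator.concentrations)
    for conc in all_concs:
        _sign_row("freq_change", f"{conc:g}", _col(conc, "freq_change_hz"))
    for hi, lo in zip(all_concs[1:], all_concs[:-1]):
        _sign_row("normalized_min", f"{hi:g} vs {lo:g}",
                  _col(hi, "normalized_min") - _col(lo, "normalized_min"))
    control = all_concs[0]
    for conc in concentrations:
        _sign_row("chirp_increase_vs_control", f"{conc:g} vs {control:g}",
                  _col(conc, "chirp_increase") - _col(control, "chirp_increase"))
    import itertools
    for lo, hi in itertools.combinations(concentrations, 2):
        _sign_row("chirp_increase_between_doses", f"{hi:g} vs {lo:g}",
                  _col(hi, "chirp_increase") - _col(lo, "chirp_increase"))
    sign_tests = pd.DataFrame(sign_rows)

    # split-plot mixed model on the normalized post-treatment grid
    records = []
    for (fid, conc), res in per_trial_results.items():
        norm = res["normalized"].post
        for k, y in enumerate(norm.values, start=1):
            records.append((fid, conc, k, y))
    frame = make_mixed_model_frame(records)
    mixed_model: dict = {}
    recovery_times: dict[float, dict] = {}
    try:
        fit = fit_mixed_model(frame)
        mixed_model = dataclasses.asdict(fit)
    except (RuntimeError, ValueError) as exc:
        mixed_model = {"error": str(exc)}
    k_max = int(frame["k"].max()) if len(frame) else 0
    for conc in concentrations:
        sub = frame[frame["concentration_ul_per_l"].isin([control, conc])]
        if k_max <= config.recovery_window_len:
            recovery_times[conc] = {"not_computed": "post grid shorter than one window"}
            continue
        try:
            jt = joint_concentration_test(sub)
            rt = recovery_time(sub, window_len=config.recovery_window_len,
                               alpha=config.alpha)
            recovery_times[conc] = {
                "joint_p_overall": jt.p_value,
                "t_r_min": rt.t_r_min, "r_index": rt.r_index,
                "recovered": rt.recovered,
            }
        except (RuntimeError, ValueError) as exc:
            recovery_times[conc] = {"error": str(exc)}

    report = RunReport(per_trial=per_trial, recovery_params=recovery_params,
                       sign_tests=sign_tests, mixed_model=mixed_model,
                       recovery_times=recovery_times, config=config)
    if outdir is not None:
        per_trial.to_csv(outdir / "per_trial.csv", index=False)
        recovery_params.to_csv(outdir / "recovery_params.csv", index=False)
        sign_tests.to_csv(outdir / "sign_tests.csv", index=False)
        (outdir / "report.json").write_text(report.to_json())
    log.info("stage=done dt=%.1fs", time.time() - t_start)
    return report
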