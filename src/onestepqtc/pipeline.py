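"""End-to-end study analysis: beats -> filtered pairs -> models -> report.

This is the glue the CLI drives.  Given a manifest plus per-session beat
tables it runs, per crossover pair:

* plausibility filtering and minute/5-min binning;
* the one-step model (per-hour own-session slopes, 5-min QTc, pooled
  window deltas across animals);
* optionally the conventional LogQTRR / LinQTHR models (vehicle circadian
  slope applied to both sessions, hourly QTc, per-animal hourly deltas);
* hourly heart-rate changes and the per-hour treated-vs-vehicle slope
  comparison of the one-step betas.

and condenses everything into :class:`~onestepqtc.effect_stats.StudyReport`
objects, one per model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import conventional, effect_stats, onestep, preprocess
from .conventional import CorrectionConfig
from .effect_stats import ClassificationConfig, StudyReport
from .onestep import OneStepConfig
from .preprocess import PlausibilityLimits
from .telemetry_io import StudyManifest

log = logging.getLogger(__name__)

ALL_MODELS = ("onestep", "linqthr", "logqtrr")
MODES = ("dqtc", "ddqtc")


@dataclass
class AnalysisConfig:
    limits: PlausibilityLimits = field(default_factory=PlausibilityLimits)
    min_beats_minute: int = preprocess.MIN_BEATS_MINUTE
    min_beats_window: int = preprocess.MIN_BEATS_WINDOW
    min_minutes_hour: int = conventional.MIN_MINUTES_HOUR
    circadian_min_points: int = conventional.MIN_POINTS_CIRCADIAN
    circadian_min_span_h: float = conventional.MIN_SPAN_HOURS
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    onestep: OneStepConfig = field(default_factory=OneStepConfig)
    classification: ClassificationConfig = field(
        default_factory=ClassificationConfig)


@dataclass
class StudyResult:
    """Everything one analysis run produced."""

    study_id: str
    mode: str
    reports: dict[str, StudyReport]
    pooled_onestep: pd.DataFrame          # long per-window deltas (one-step)
    conventional_deltas: dict[str, pd.DataFrame]  # model -> per-animal hourly
    slope_table: pd.DataFrame             # per animal/session/hour betas
    slope_test: pd.DataFrame              # per-hour paired beta comparison
    dhr: pd.DataFrame                     # per-animal hourly HR change
    rejections: dict[str, dict[str, int]]
    onestep_animal_effects: list = field(default_factory=list)


def _prepare_session(beats: pd.DataFrame, cfg: AnalysisConfig):
    kept, rejections = preprocess.filter_beats(beats, cfg.limits)
    minutes = preprocess.minute_pairs(kept, cfg.min_beats_minute)
    windows = preprocess.window_pairs(kept, cfg.min_beats_window)
    return minutes, windows, rejections


def analyze_study(manifest: StudyManifest,
                  beats: dict[str, pd.DataFrame],
                  models=ALL_MODELS,
                  mode: str = "dqtc",
                  cfg: AnalysisConfig | None = None) -> StudyResult:
    """Run the full analysis for one crossover study."""
    cfg = cfg or AnalysisConfig()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    models = tuple(models)
    for m in models:
        if m not in ALL_MODELS:
            raise ValueError(f"unknown model {m!r}")

    prepared = {}
    rejections = {}
    for sess in manifest.sessions:
        minutes, windows, rej = _prepare_session(beats[sess.session_id], cfg)
        prepared[sess.session_id] = (sess, minutes, windows)
        rejections[sess.session_id] = rej

    onestep_deltas: dict[str, pd.DataFrame] = {}
    conv_delta_rows: dict[str, list] = {m: [] for m in models
                                        if m != "onestep"}
    slope_rows = []
    slope_pair_rows = []
    dhr_rows = []

    for pair in manifest.pairing:
        sess_v, min_v, win_v = prepared[pair.vehicle]
        sess_t, min_t, win_t = prepared[pair.treated]

        # hourly mean HR change, time-matched within animal
        hr_v = preprocess.hourly_means(min_v, sess_v.dose_time_s,
                                       ("hr",), cfg.min_minutes_hour)
        hr_t = preprocess.hourly_means(min_t, sess_t.dose_time_s,
                                       ("hr",), cfg.min_minutes_hour)
        hr_m = hr_v.merge(hr_t, on="hour_index", suffixes=("_v", "_t"))
        for _, row in hr_m.iterrows():
            dhr_rows.append((pair.animal_id, int(row["hour_index"]),
                             row["hr_t"] - row["hr_v"]))

        if "onestep" in models:
            qtc_by_role = {}
            for sess, minutes, windows in ((sess_v, min_v, win_v),
                                           (sess_t, min_t, win_t)):
                slopes = onestep.hourly_slopes(
                    minutes, sess.dose_time_s, pair.animal_id,
                    sess.session_id, cfg.onestep)
                for _, s in slopes.iterrows():
                    slope_rows.append((pair.animal_id, sess.session_id,
                                       sess.role, int(s["hour_index"]),
                                       s["beta"], int(s["n"]), s["hr_sd"],
                                       bool(s["fallback"])))
                qtc_by_role[sess.role] = onestep.onestep_qtc(
                    windows, slopes, sess.dose_time_s, cfg.correction)
            if mode == "dqtc":
                onestep_deltas[pair.animal_id] = onestep.delta_qtc(
                    qtc_by_role["vehicle"], qtc_by_role["treated"])
            else:
                try:
                    onestep_deltas[pair.animal_id] = onestep.delta_delta_qtc(
                        qtc_by_role["vehicle"], qtc_by_role["treated"],
                        cfg.onestep.min_baseline_windows)
                except ValueError as exc:
                    log.warning("animal %s excluded from the double delta: "
                                "%s", pair.animal_id, exc)

        for model in conv_delta_rows:
            slope = conventional.circadian_slope(
                min_v, model, pair.animal_id, sess_v.session_id,
                cfg.circadian_min_points, cfg.circadian_min_span_h)
            hq_v = conventional.hourly_qtc_conventional(
                min_v, slope, sess_v.dose_time_s, cfg.correction,
                cfg.min_minutes_hour)
            hq_t = conventional.hourly_qtc_conventional(
                min_t, slope, sess_t.dose_time_s, cfg.correction,
                cfg.min_minutes_hour)
            merged = hq_v.merge(hq_t, on="hour_index", suffixes=("_v", "_t"))
            d = merged["qtc_t"].to_numpy() - merged["qtc_v"].to_numpy()
            if mode == "ddqtc":
                base = merged["hour_index"] == 0
                if not base.any():
                    log.warning("animal %s, model %s: no baseline hour for "
                                "the double delta; animal excluded",
                                pair.animal_id, model)
                    continue
                d = d - float(d[base.to_numpy()][0])
            for h, val in zip(merged["hour_index"], d):
                conv_delta_rows[model].append(
                    (pair.animal_id, int(h), float(val)))

    # pooled tables ---------------------------------------------------------
    pooled = onestep.pool_hours(onestep_deltas) if "onestep" in models \
        else pd.DataFrame(columns=["animal_id", "window_rel", "hour_index",
                                   "dqtc"])
    conv_deltas = {
        m: pd.DataFrame(rows, columns=["animal_id", "hour_index", "dqtc"])
        for m, rows in conv_delta_rows.items()
    }
    slope_table = pd.DataFrame(
        slope_rows, columns=["animal_id", "session_id", "role", "hour_index",
                             "beta", "n", "hr_sd", "fallback"])
    dhr = pd.DataFrame(dhr_rows, columns=["animal_id", "hour_index", "dhr"])

    if not slope_table.empty:
        wide = slope_table.pivot_table(index=["animal_id", "hour_index"],
                                       columns="role", values="beta",
                                       aggfunc="first").reset_index()
        if {"vehicle", "treated"} <= set(wide.columns):
            slope_pair_rows = wide.rename(
                columns={"vehicle": "beta_vehicle",
                         "treated": "beta_treated"})
    if isinstance(slope_pair_rows, list):
        slope_pair_rows = pd.DataFrame(
            columns=["animal_id", "hour_index", "beta_vehicle",
                     "beta_treated"])
    slope_test = effect_stats.slope_effect_test(slope_pair_rows) \
        if len(slope_pair_rows) else pd.DataFrame(
            columns=["hour_index", "n_pairs", "dbeta_mean", "p", "degenerate"])

    # reports ---------------------------------------------------------------
    try:
        hr_change = effect_stats.max_hr_change(dhr, cfg.classification)
    except effect_stats.NoUsableHoursError:
        hr_change = None

    reports: dict[str, StudyReport] = {}
    post_hours = None  # hours >= 1 only; baseline and pre-dose excluded
    animal_effects: list = []
    for model in models:
        if model == "onestep":
            sub = pooled[pooled["hour_index"] >= 1]
            effects = effect_stats.effects_from_samples(sub, "dqtc", mode)
            per_animal = (sub.groupby(["hour_index", "animal_id"])["dqtc"]
                          .mean().reset_index())
            animal_effects = effect_stats.effects_from_samples(
                per_animal, "dqtc", mode)
        else:
            sub = conv_deltas[model]
            sub = sub[sub["hour_index"] >= 1]
            effects = effect_stats.effects_from_samples(sub, "dqtc", mode)
        report = StudyReport(
            study_id=manifest.study_id, model=model, mode=mode,
            effects=effects, max_hr_change=hr_change,
            n_animals=len(manifest.pairing),
        )
        try:
            report.peak_hour, report.peak = effect_stats.peak_effect(
                effects, cfg.classification)
            report.classification = effect_stats.classify(
                effects, cfg.classification)
        except effect_stats.NoUsableHoursError as exc:
            log.warning("study %s, model %s: %s", manifest.study_id, model,
                        exc)
            report.classification = "inconclusive"
        reports[model] = report
        post_hours = post_hours or [e.hour_index for e in effects]

    return StudyResult(
        study_id=manifest.study_id, mode=mode, reports=reports,
        pooled_onestep=pooled, conventional_deltas=conv_deltas,
        slope_table=slope_table, slope_test=slope_test, dhr=dhr,
        rejections=rejections, onestep_animal_effects=animal_effects,
    )
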