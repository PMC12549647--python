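"""The one-step QTc model.

Instead of borrowing a correction slope from a drug-free period, the
one-step model estimates the QT/HR slope *individually, every hour, from
the session being corrected*: OLS of QT on HR over the (up to 60) minute
pairs of that dose-relative hour.  QTc values are then computed from 5-min
window means with the hour's own slope,

    QTc = QT - beta_hour * (HR - HRref),    HRref = 80 bpm,

giving 12 QTc values per hour per animal (48 per hour in a four-animal
study once pooled).  Estimating treated-session slopes from treated data
is the model's central assumption: drugs that change heart rate or the
QT/HR relationship are corrected with the relationship actually in force,
which is what reveals prolongation concealed under fixed-slope models.

Treatment effects are the time-matched window differences within animal:

* single delta:  ``dQTc(w) = QTc_treated(w) - QTc_vehicle(w)``
* double delta:  ``ddQTc(w) = (QTc_t(w) - base_t) - (QTc_v(w) - base_v)``
  where each baseline is that session's mean QTc over the hour preceding
  administration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conventional import CorrectionConfig, SlopeEstimate, ols_slope, SlopeFitError
from .preprocess import hour_of_minute, hour_of_window_rel, window_rel_index

log = logging.getLogger(__name__)

#: an hourly fit needs at least this many of the 60 possible minutes and
#: this much heart-rate spread to be trusted; failing hours fall back to
#: the session's median hourly slope (flagged)
MIN_PAIRS_HOUR = 45
MIN_HR_SD = 1.0

#: minimum baseline-hour windows required per session for the double delta
MIN_BASELINE_WINDOWS = 6


@dataclass
class OneStepConfig:
    min_pairs_hour: int = MIN_PAIRS_HOUR
    min_hr_sd: float = MIN_HR_SD
    min_baseline_windows: int = MIN_BASELINE_WINDOWS


def hourly_slope(pairs: pd.DataFrame, animal_id: str = "",
                 session_id: str = "", hour_index: int = 0,
                 cfg: OneStepConfig | None = None) -> SlopeEstimate:
    """OLS slope of QT on HR for the minute pairs of one hour.

    Raises :class:`SlopeFitError` when the hour has too few pairs or a
    flat regressor; callers handle the fallback.
    """
    cfg = cfg or OneStepConfig()
    hr = pairs["hr"].to_numpy(dtype=float)
    qt = pairs["qt"].to_numpy(dtype=float)
    if len(pairs) < cfg.min_pairs_hour:
        raise SlopeFitError(
            f"hour {hour_index}: {len(pairs)} minute pairs "
            f"< {cfg.min_pairs_hour}")
    hr_sd = float(np.std(hr))
    if hr_sd < cfg.min_hr_sd:
        raise SlopeFitError(
            f"hour {hour_index}: HR spread {hr_sd:.2f} bpm "
            f"< {cfg.min_hr_sd}")
    beta, intercept = ols_slope(hr, qt)
    return SlopeEstimate(
        animal_id=animal_id, session_id=session_id, scope=str(hour_index),
        model="onestep", beta=beta, intercept=intercept,
        n_points=len(pairs), hr_sd=hr_sd,
    )


def hourly_slopes(minutes: pd.DataFrame, dose_time_s: float,
                  animal_id: str = "", session_id: str = "",
                  cfg: OneStepConfig | None = None) -> pd.DataFrame:
    """Per-hour one-step slopes for one session.

    Hours failing the fit preconditions receive the session's median valid
    hourly slope with ``fallback=True``; this keeps the 12-value QTc grid
    without inventing per-hour information.  Columns: hour_index, beta,
    intercept, n, hr_sd, fallback.
    """
    cfg = cfg or OneStepConfig()
    hours = hour_of_minute(minutes["minute_index"].to_numpy(), dose_time_s)
    rows = []
    for h in np.unique(hours):
        sub = minutes.loc[hours == h]
        try:
            est = hourly_slope(sub, animal_id, session_id, int(h), cfg)
            rows.append((int(h), est.beta, est.intercept, est.n_points,
                         est.hr_sd, False))
        except SlopeFitError as exc:
            log.debug("%s/%s: %s (fallback)", animal_id, session_id, exc)
            rows.append((int(h), np.nan, np.nan, len(sub),
                         float(np.std(sub["hr"])), True))
    out = pd.DataFrame(rows, columns=["hour_index", "beta", "intercept",
                                      "n", "hr_sd", "fallback"])
    valid = out.loc[~out["fallback"], "beta"]
    if valid.empty:
        raise SlopeFitError(
            f"{animal_id}/{session_id}: no hour passed the slope "
            f"preconditions; session unusable")
    out.loc[out["fallback"], "beta"] = float(valid.median())
    return out


def onestep_qtc(windows: pd.DataFrame, slopes: pd.DataFrame,
                dose_time_s: float,
                cfg: CorrectionConfig | None = None) -> pd.DataFrame:
    """One-step QTc for each 5-min window of a session.

    Each window is corrected with the slope of the dose-relative hour that
    contains it; windows whose hour has no slope row are dropped (logged).
    Columns: window_rel, hour_index, qtc, hr, n_beats, beta_used, fallback.
    """
    cfg = cfg or CorrectionConfig()
    w_rel = window_rel_index(windows["window_index"].to_numpy(), dose_time_s)
    hours = hour_of_window_rel(w_rel)
    df = windows.assign(window_rel=w_rel, hour_index=hours)
    merged = df.merge(slopes[["hour_index", "beta", "fallback"]],
                      on="hour_index", how="left")
    missing = merged["beta"].isna()
    if missing.any():
        log.info("onestep_qtc: %d windows without an hourly slope dropped",
                 int(missing.sum()))
        merged = merged.loc[~missing]
    qtc = (merged["qt"].to_numpy()
           - merged["beta"].to_numpy()
           * (merged["hr"].to_numpy() - cfg.hr_ref))
    return pd.DataFrame({
        "window_rel": merged["window_rel"].to_numpy(),
        "hour_index": merged["hour_index"].to_numpy(),
        "qtc": qtc,
        "hr": merged["hr"].to_numpy(),
        "n_beats": merged["n_beats"].to_numpy(),
        "beta_used": merged["beta"].to_numpy(),
        "fallback": merged["fallback"].to_numpy(),
    })


def delta_qtc(vehicle_qtc: pd.DataFrame,
              treated_qtc: pd.DataFrame) -> pd.DataFrame:
    """Time-matched single-delta QTc per 5-min window within one animal.

    Windows are matched on the dose-relative window index; unmatched
    windows are dropped (counted to the log).  Columns: window_rel,
    hour_index, dqtc, qtc_vehicle, qtc_treated, dhr.
    """
    merged = vehicle_qtc.merge(treated_qtc, on="window_rel",
                               suffixes=("_v", "_t"))
    n_unmatched = (len(vehicle_qtc) + len(treated_qtc) - 2 * len(merged))
    if n_unmatched:
        log.debug("delta_qtc: %d unmatched windows dropped", n_unmatched)
    return pd.DataFrame({
        "window_rel": merged["window_rel"].to_numpy(),
        "hour_index": merged["hour_index_v"].to_numpy(),
        "dqtc": merged["qtc_t"].to_numpy() - merged["qtc_v"].to_numpy(),
        "qtc_vehicle": merged["qtc_v"].to_numpy(),
        "qtc_treated": merged["qtc_t"].to_numpy(),
        "dhr": merged["hr_t"].to_numpy() - merged["hr_v"].to_numpy(),
    })


def session_baseline(qtc: pd.DataFrame,
                     min_windows: int = MIN_BASELINE_WINDOWS) -> float:
    """Mean QTc over the baseline hour (hour 0) of one session."""
    base = qtc.loc[qtc["hour_index"] == 0, "qtc"]
    if len(base) < min_windows:
        raise ValueError(
            f"baseline hour has {len(base)} QTc windows "
            f"< required {min_windows}")
    return float(base.mean())


def delta_delta_qtc(vehicle_qtc: pd.DataFrame, treated_qtc: pd.DataFrame,
                    min_baseline_windows: int = MIN_BASELINE_WINDOWS,
                    ) -> pd.DataFrame:
    """Double-delta QTc: single delta after per-session baseline removal."""
    base_v = session_baseline(vehicle_qtc, min_baseline_windows)
    base_t = session_baseline(treated_qtc, min_baseline_windows)
    out = delta_qtc(vehicle_qtc, treated_qtc)
    out["dqtc"] = out["dqtc"] - (base_t - base_v)
    return out


def pool_hours(deltas_by_animal: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool per-window deltas across animals into one long table.

    Returns columns animal_id, window_rel, hour_index, dqtc.  With four
    animals and a complete hour the per-hour count is 48 (12 windows per
    animal); partial coverage simply yields fewer rows.
    """
    frames = []
    for animal_id, df in deltas_by_animal.items():
        frames.append(df.assign(animal_id=animal_id))
    if not frames:
        return pd.DataFrame(
            columns=["animal_id", "window_rel", "hour_index", "dqtc"])
    pooled = pd.concat(frames, ignore_index=True)
    return pooled[["animal_id", "window_rel", "hour_index", "dqtc"]
                  + [c for c in pooled.columns if c == "dhr"]]
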