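"""Beat-level preprocessing: plausibility filtering and time binning.

Beat-to-beat heart rate is derived as ``HR = 60000 / RR`` (RR in ms, HR in
bpm) and then averaged: a minute pair is the mean of the per-beat HR and QT
values of one [60k, 60(k+1)) second bin, a window pair the same over 300 s
bins (12 windows per complete hour).  Averaging per-beat HR — rather than
taking 60000 over the mean RR — is deliberate: the rate is defined beat to
beat first and aggregated second.

Bins are anchored at session start (t = 0).  Helpers at the bottom
re-express minute/window/hour indices on the dose-relative grid used by the
analysis stages: post-dose hour ``h`` covers ``[dose + (h-1)*3600,
dose + h*3600)`` so hour 1 is the first post-dose hour and hour 0 the
baseline hour immediately preceding administration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60.0
SECONDS_PER_WINDOW = 300.0
WINDOWS_PER_HOUR = 12

#: default minimum beat counts for a usable minute / 5-min window
MIN_BEATS_MINUTE = 30
MIN_BEATS_WINDOW = 100


def beat_hr(rr):
    """Instantaneous heart rate in bpm from an RR interval in ms."""
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(rr_arr <= 0):
        raise ValueError("RR interval must be positive")
    out = 60000.0 / rr_arr
    return float(out) if np.isscalar(rr) or out.ndim == 0 else out


@dataclass
class PlausibilityLimits:
    """Physiological plausibility bracket for beagle-dog beats.

    Defaults bracket canine physiology generously (30–200 bpm; QT well
    clear of both measurement floor and the longest credible canine QT).
    """

    rr_min: float = 300.0
    rr_max: float = 2000.0
    qt_min: float = 100.0
    qt_max: float = 450.0


def filter_beats(series: pd.DataFrame,
                 limits: PlausibilityLimits | None = None,
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop implausible beats; return the kept beats and a rejection log.

    Each rejected beat is counted under the first rule it violates, in the
    order rr_low, rr_high, qt_low, qt_high, qt_ge_rr.
    """
    limits = limits or PlausibilityLimits()
    rr = series["rr_ms"].to_numpy()
    qt = series["qt_ms"].to_numpy()

    reasons = (
        ("rr_low", rr < limits.rr_min),
        ("rr_high", rr > limits.rr_max),
        ("qt_low", qt < limits.qt_min),
        ("qt_high", qt > limits.qt_max),
        ("qt_ge_rr", qt >= rr),
    )
    rejected = np.zeros(len(series), dtype=bool)
    counts: dict[str, int] = {}
    for name, mask in reasons:
        new = mask & ~rejected
        counts[name] = int(new.sum())
        rejected |= mask
    kept = series.loc[~rejected].reset_index(drop=True)
    counts["total_rejected"] = int(rejected.sum())
    counts["kept"] = len(kept)
    if counts["total_rejected"]:
        log.info("filter_beats: rejected %d of %d beats (%s)",
                 counts["total_rejected"], len(series),
                 {k: v for k, v in counts.items() if v and k not in
                  ("kept", "total_rejected")})
    return kept, counts


def _binned_pairs(series: pd.DataFrame, width_s: float, min_beats: int,
                  index_name: str) -> pd.DataFrame:
    t = series["time_s"].to_numpy()
    if len(t) == 0:
        return pd.DataFrame(
            {index_name: np.array([], dtype=np.int64),
             "hr": [], "qt": [], "n_beats": np.array([], dtype=np.int64)})
    idx = np.floor_divide(t, width_s).astype(np.int64)
    nbin = int(idx.max()) + 1
    cnt = np.bincount(idx, minlength=nbin)
    hr = 60000.0 / series["rr_ms"].to_numpy()
    hr_sum = np.bincount(idx, weights=hr, minlength=nbin)
    qt_sum = np.bincount(idx, weights=series["qt_ms"].to_numpy(),
                         minlength=nbin)
    keep = cnt >= max(min_beats, 1)
    which = np.nonzero(keep)[0]
    return pd.DataFrame({
        index_name: which,
        "hr": hr_sum[keep] / cnt[keep],
        "qt": qt_sum[keep] / cnt[keep],
        "n_beats": cnt[keep],
    })


def minute_pairs(series: pd.DataFrame,
                 min_beats: int = MIN_BEATS_MINUTE) -> pd.DataFrame:
    """Per-minute mean (HR, QT) pairs; minutes with < min_beats omitted."""
    return _binned_pairs(series, SECONDS_PER_MINUTE, min_beats, "minute_index")


def window_pairs(series: pd.DataFrame,
                 min_beats: int = MIN_BEATS_WINDOW) -> pd.DataFrame:
    """Per-5-minute mean (HR, QT) pairs; windows with < min_beats omitted."""
    return _binned_pairs(series, SECONDS_PER_WINDOW, min_beats, "window_index")


# ---------------------------------------------------------------------------
# dose-relative re-indexing
# ---------------------------------------------------------------------------

def _grid_offset(dose_time_s: float, width_s: float, what: str) -> int:
    offset = dose_time_s / width_s
    rounded = int(round(offset))
    if abs(offset - rounded) > 1e-6:
        log.warning("dose_time_s=%.3f is not aligned on the %s grid; "
                    "rounding to the nearest bin edge", dose_time_s, what)
    return rounded


def hour_of_minute(minute_index, dose_time_s: float):
    """Dose-relative hour of a session-anchored minute index.

    Hour 1 = first post-dose hour, hour 0 = baseline hour before dosing.
    """
    om = _grid_offset(dose_time_s, SECONDS_PER_MINUTE, "minute")
    m_rel = np.asarray(minute_index, dtype=np.int64) - om
    return m_rel // 60 + 1


def window_rel_index(window_index, dose_time_s: float):
    """Dose-relative 5-min window index (0 = first post-dose window)."""
    ow = _grid_offset(dose_time_s, SECONDS_PER_WINDOW, "window")
    return np.asarray(window_index, dtype=np.int64) - ow


def hour_of_window_rel(window_rel):
    """Dose-relative hour containing a dose-relative window index."""
    return np.asarray(window_rel, dtype=np.int64) // WINDOWS_PER_HOUR + 1


def hourly_means(minutes: pd.DataFrame, dose_time_s: float,
                 value_cols: tuple[str, ...] = ("hr", "qt"),
                 min_minutes: int = 30) -> pd.DataFrame:
    """Dose-relative hourly means of per-minute values.

    Hours with fewer than ``min_minutes`` contributing minutes are marked
    missing (omitted from the result).
    """
    if len(minutes) == 0:
        return pd.DataFrame(columns=["hour_index", *value_cols, "n_minutes"])
    hours = hour_of_minute(minutes["minute_index"].to_numpy(), dose_time_s)
    df = minutes.assign(hour_index=hours)
    grouped = df.groupby("hour_index", sort=True)
    out = grouped[list(value_cols)].mean()
    out["n_minutes"] = grouped.size()
    out = out[out["n_minutes"] >= min_minutes].reset_index()
    return out
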