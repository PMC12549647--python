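"""Conventional individual QT correction models (LogQTRR, LinQTHR).

Both models estimate a single per-animal correction slope from the minute
pairs of the drug-free (vehicle) session over the circadian cycle, then
apply it to every minute of *both* sessions of the crossover pair:

* LogQTRR: ``QTc = 10^(log10 QT - beta * (log10 RR - log10 RRref))``,
  equivalently ``QT * (RRref / RR)^beta``, with ``RRref = 750 ms`` in dogs
  (the QT/RR relationship is curved at short RR, hence the log-log
  linearization).
* LinQTHR: ``QTc = QT - beta * (HR - HRref)`` with ``HRref = 80 bpm``
  (the QT/HR relationship is close to linear in dogs).

Reusing the vehicle-period slope for the treated session is the defining
property of these models and the mechanism behind "concealed" QTc
prolongation when a drug itself changes heart rate or the QT/HR slope.
Per-minute QTc values are finally averaged per dose-relative hour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import hourly_means

log = logging.getLogger(__name__)

MODELS = ("logqtrr", "linqthr")

#: minimum number of minute pairs and circadian span for a circadian fit
MIN_POINTS_CIRCADIAN = 600
MIN_SPAN_HOURS = 20.0
#: minimum minutes for a usable hourly QTc mean
MIN_MINUTES_HOUR = 30


class SlopeFitError(ValueError):
    """A regression precondition failed (too few points, flat regressor)."""


@dataclass
class CorrectionConfig:
    """Reference point of the corrections: 750 ms RR == 80 bpm HR."""

    rr_ref: float = 750.0
    hr_ref: float = 80.0

    def __post_init__(self):
        if self.rr_ref <= 0 or self.hr_ref <= 0:
            raise ValueError("reference values must be positive")


@dataclass
class SlopeEstimate:
    """A fitted QT/HR (or log QT / log RR) slope with provenance."""

    animal_id: str
    session_id: str
    scope: str            # "circadian" or the dose-relative hour index
    model: str            # "logqtrr" | "linqthr" | "onestep"
    beta: float
    intercept: float
    n_points: int
    hr_sd: float          # spread of the regressor, bpm (or log10 RR units)
    fallback: bool = False


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares slope and intercept of y on x.

    Centered closed form: ``beta = sum(xc * y) / sum(xc^2)`` with
    ``xc = x - mean(x)``; numerically robust for regressors far from 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x.mean()
    xc = x - xm
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise SlopeFitError("regressor has zero variance")
    beta = float(np.dot(xc, y)) / sxx
    intercept = float(y.mean() - beta * xm)
    return beta, intercept


def _regression_xy(pairs: pd.DataFrame, model: str) -> tuple[np.ndarray, np.ndarray]:
    hr = pairs["hr"].to_numpy(dtype=float)
    qt = pairs["qt"].to_numpy(dtype=float)
    if model == "linqthr":
        return hr, qt
    if model == "logqtrr":
        # RR is reconstructed from the canonical per-minute HR
        rr = 60000.0 / hr
        return np.log10(rr), np.log10(qt)
    raise ValueError(f"unknown model {model!r}")


def circadian_slope(pairs: pd.DataFrame, model: str,
                    animal_id: str = "", session_id: str = "",
                    min_points: int = MIN_POINTS_CIRCADIAN,
                    min_span_hours: float = MIN_SPAN_HOURS) -> SlopeEstimate:
    """Per-animal correction slope over the circadian cycle.

    Fits OLS of log10(QT) on log10(RR) (logqtrr) or QT on HR (linqthr) to
    the minute pairs of a vehicle session.  The fit must cover at least
    ``min_span_hours`` of the day and ``min_points`` minutes; there is no
    fallback at circadian scope — an unusable vehicle day is an error.
    """
    if len(pairs) < min_points:
        raise SlopeFitError(
            f"circadian fit needs >= {min_points} minute pairs, "
            f"got {len(pairs)}")
    minutes = pairs["minute_index"].to_numpy()
    span_h = (minutes.max() - minutes.min()) / 60.0
    if span_h < min_span_hours:
        raise SlopeFitError(
            f"circadian fit needs >= {min_span_hours} h of vehicle data, "
            f"got {span_h:.1f} h")
    x, y = _regression_xy(pairs, model)
    beta, intercept = ols_slope(x, y)
    return SlopeEstimate(
        animal_id=animal_id, session_id=session_id, scope="circadian",
        model=model, beta=beta, intercept=intercept,
        n_points=len(pairs), hr_sd=float(np.std(x)),
    )


def qtc_logqtrr(qt, rr, beta: float, cfg: CorrectionConfig | None = None):
    """Log-model corrected QT: ``qt * (rr_ref / rr)^beta`` (ms)."""
    cfg = cfg or CorrectionConfig()
    qt_arr = np.asarray(qt, dtype=float)
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(qt_arr <= 0) or np.any(rr_arr <= 0):
        raise ValueError("qt and rr must be positive")
    out = qt_arr * (cfg.rr_ref / rr_arr) ** beta
    return float(out) if out.ndim == 0 else out


def qtc_linqthr(qt, hr, beta: float, cfg: CorrectionConfig | None = None):
    """Linear-model corrected QT: ``qt - beta * (hr - hr_ref)`` (ms)."""
    cfg = cfg or CorrectionConfig()
    qt_arr = np.asarray(qt, dtype=float)
    if np.any(qt_arr <= 0):
        raise ValueError("qt must be positive")
    out = qt_arr - beta * (np.asarray(hr, dtype=float) - cfg.hr_ref)
    return float(out) if out.ndim == 0 else out


def minute_qtc(pairs: pd.DataFrame, slope: SlopeEstimate,
               cfg: CorrectionConfig | None = None) -> pd.DataFrame:
    """Per-minute QTc from minute pairs under a circadian slope."""
    cfg = cfg or CorrectionConfig()
    hr = pairs["hr"].to_numpy(dtype=float)
    qt = pairs["qt"].to_numpy(dtype=float)
    if slope.model == "linqthr":
        qtc = qtc_linqthr(qt, hr, slope.beta, cfg)
    elif slope.model == "logqtrr":
        qtc = qtc_logqtrr(qt, 60000.0 / hr, slope.beta, cfg)
    else:
        raise ValueError(f"not a conventional model: {slope.model!r}")
    return pairs.assign(qtc=qtc)


def hourly_qtc_conventional(pairs: pd.DataFrame, slope: SlopeEstimate,
                            dose_time_s: float,
                            cfg: CorrectionConfig | None = None,
                            min_minutes: int = MIN_MINUTES_HOUR,
                            ) -> pd.DataFrame:
    """Hourly mean conventional QTc for one session of one animal.

    Per-minute QTc values are averaged over each dose-relative hour with at
    least ``min_minutes`` minutes present; columns: hour_index, qtc, hr,
    n_minutes.
    """
    if slope.scope != "circadian":
        raise ValueError("conventional correction requires a circadian slope")
    with_qtc = minute_qtc(pairs, slope, cfg)
    return hourly_means(with_qtc, dose_time_s, value_cols=("qtc", "hr"),
                        min_minutes=min_minutes)
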