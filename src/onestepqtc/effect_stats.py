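"""TQT-style inference on hourly treatment effects.

For each post-dose hour the mean delta-QTc is reported with a one-sided
95% confidence interval built from the central t distribution:

    LSD = t(0.95, n-1) * sd / sqrt(n),   lb = mean - LSD,  ub = mean + LSD

The LSD (least significant difference) is the half-width of that interval
— the smallest mean effect distinguishable from zero under the study's
conditions.  Classification mirrors thorough-QT practice: an hour whose
lower bound reaches 5 ms is a positive signal; a study whose upper bounds
all stay below 10 ms is negative at TQT criteria; anything else is
inconclusive.  No multiplicity adjustment is applied across hours, which
matches TQT practice.

Two sampling conventions coexist deliberately:

* one-step model: the samples are the pooled 5-min deltas across animals
  (n = 48 for four complete animals).  The 12 per-animal windows are not
  independent — that pseudo-replication is a documented, accepted property
  of the method, which uses autonomic within-hour variability to mimic
  the between-subject variability of a clinical trial.  An animal-level
  (n = animals) interval is also provided for comparison.
* conventional models: one hourly delta per animal, interval across
  animals (n = number of animals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

POSITIVE_LB_MS = 5.0      # clinical positive-control threshold
NEGATIVE_UB_MS = 10.0     # low-risk upper-bound criterion
PEAK_WINDOW = (1, 6)      # hours scanned for the peak effect


class NoUsableHoursError(ValueError):
    pass


@dataclass
class ClassificationConfig:
    positive_lb_threshold: float = POSITIVE_LB_MS
    negative_ub_threshold: float = NEGATIVE_UB_MS
    peak_window: tuple[int, int] = PEAK_WINDOW

    def __post_init__(self):
        if self.positive_lb_threshold <= 0 or self.negative_ub_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def hours(self, available) -> list[int]:
        lo, hi = self.peak_window
        return [h for h in available if lo <= h <= hi]


@dataclass
class HourlyEffect:
    hour_index: int
    mode: str            # "dqtc" | "ddqtc"
    n: int
    mean: float
    lb: float
    ub: float
    lsd: float


@dataclass
class StudyReport:
    """Per-study, per-model summary row (one table row per study)."""

    study_id: str
    model: str
    mode: str
    effects: list[HourlyEffect] = field(default_factory=list)
    peak_hour: int | None = None
    peak: HourlyEffect | None = None
    max_hr_change: float | None = None
    classification: str = "inconclusive"
    n_animals: int = 0

    def effect(self, hour: int) -> HourlyEffect | None:
        for e in self.effects:
            if e.hour_index == hour:
                return e
        return None


def hourly_ci(samples, hour_index: int = 0,
              mode: str = "dqtc") -> HourlyEffect | None:
    """Mean and symmetric one-sided 95% bounds for one hour's samples.

    Returns None when fewer than two samples are available (hour
    unusable).
    """
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        return None
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    lsd = float(stats.t.ppf(0.95, n - 1) * sd / np.sqrt(n))
    return HourlyEffect(hour_index=int(hour_index), mode=mode, n=n,
                        mean=mean, lb=mean - lsd, ub=mean + lsd, lsd=lsd)


def effects_from_samples(df: pd.DataFrame, value_col: str = "dqtc",
                         mode: str = "dqtc",
                         hours=None) -> list[HourlyEffect]:
    """Hourly effects from a long table with hour_index + value columns."""
    effects = []
    for h, sub in df.groupby("hour_index", sort=True):
        if hours is not None and h not in hours:
            continue
        eff = hourly_ci(sub[value_col].to_numpy(), int(h), mode)
        if eff is not None:
            effects.append(eff)
    return effects


def classify(effects: list[HourlyEffect],
             cfg: ClassificationConfig | None = None) -> str:
    """TQT-style classification over the configured peak window."""
    cfg = cfg or ClassificationConfig()
    usable = [e for e in effects
              if cfg.peak_window[0] <= e.hour_index <= cfg.peak_window[1]]
    if not usable:
        raise NoUsableHoursError(
            f"no usable hours within {cfg.peak_window}")
    if any(e.lb >= cfg.positive_lb_threshold for e in usable):
        return "positive"
    if all(e.ub < cfg.negative_ub_threshold for e in usable):
        return "negative_tqt"
    return "inconclusive"


def peak_effect(effects: list[HourlyEffect],
                cfg: ClassificationConfig | None = None,
                ) -> tuple[int, HourlyEffect]:
    """Hour with the largest mean effect in the peak window (ties: earliest)."""
    cfg = cfg or ClassificationConfig()
    usable = sorted(
        (e for e in effects
         if cfg.peak_window[0] <= e.hour_index <= cfg.peak_window[1]),
        key=lambda e: e.hour_index)
    if not usable:
        raise NoUsableHoursError(f"no usable hours within {cfg.peak_window}")
    best = usable[0]
    for e in usable[1:]:
        if e.mean > best.mean:
            best = e
    return best.hour_index, best


def max_hr_change(dhr: pd.DataFrame,
                  cfg: ClassificationConfig | None = None) -> float:
    """Signed maximum-magnitude hourly heart-rate change (bpm).

    ``dhr`` is a long table with columns animal_id, hour_index, dhr
    (treated minus vehicle hourly mean HR per animal).  Per-hour means
    across animals are scanned over the peak window and the signed value
    with the largest absolute magnitude is returned.
    """
    cfg = cfg or ClassificationConfig()
    lo, hi = cfg.peak_window
    sub = dhr[(dhr["hour_index"] >= lo) & (dhr["hour_index"] <= hi)]
    if sub.empty:
        raise NoUsableHoursError("no hourly HR data in the peak window")
    per_hour = sub.groupby("hour_index")["dhr"].mean()
    return float(per_hour.loc[per_hour.abs().idxmax()])


def slope_effect_test(slope_pairs: pd.DataFrame) -> pd.DataFrame:
    """Paired per-hour test of treated vs vehicle one-step slopes.

    ``slope_pairs`` has columns animal_id, hour_index, beta_vehicle,
    beta_treated.  For each hour with at least two animal pairs, a paired
    two-sided t test of the slope difference is run.  Zero within-pair
    variance with a nonzero difference is degenerate (p reported as 0.0,
    flagged); identical slope sets give p = 1.
    Columns: hour_index, n_pairs, dbeta_mean, p, degenerate.
    """
    rows = []
    for h, sub in slope_pairs.groupby("hour_index", sort=True):
        d = (sub["beta_treated"] - sub["beta_vehicle"]).to_numpy(dtype=float)
        d = d[~np.isnan(d)]
        if len(d) < 2:
            continue
        degenerate = bool(np.ptp(d) == 0.0)
        if degenerate:
            p = 1.0 if d[0] == 0.0 else 0.0
        else:
            p = float(stats.ttest_rel(
                sub["beta_treated"], sub["beta_vehicle"]).pvalue)
        rows.append((int(h), len(d), float(d.mean()), p, degenerate))
    return pd.DataFrame(rows, columns=["hour_index", "n_pairs",
                                       "dbeta_mean", "p", "degenerate"])


def study_lsd(effects: list[HourlyEffect],
              cfg: ClassificationConfig | None = None,
              reduce: str = "median") -> float:
    """Scalar per-study LSD: reduction of the hourly LSDs over the window."""
    cfg = cfg or ClassificationConfig()
    lsds = [e.lsd for e in effects
            if cfg.peak_window[0] <= e.hour_index <= cfg.peak_window[1]]
    if not lsds:
        raise NoUsableHoursError("no usable hours for the LSD summary")
    fn = {"median": np.median, "mean": np.mean, "max": np.max}[reduce]
    return float(fn(lsds))


def lsd_summary(per_study: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Battery summary: per-study LSD per model plus a medians row.

    ``per_study`` maps study_id -> {model: lsd}.  The returned frame has
    one row per study and a final row labelled ``median``.
    """
    df = pd.DataFrame.from_dict(per_study, orient="index").sort_index()
    df.index.name = "study_id"
    medians = df.median(axis=0)
    medians.name = "median"
    return pd.concat([df, medians.to_frame().T])
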