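"""Seeded Monte Carlo experiments over the simulator + pipeline.

These are the study-level calibration runs the package uses to
characterize its own statistics: null-hour size of the one-sided interval,
recovery of an injected prolongation, the LSD contrast between the
one-step and conventional models across a study battery, and the
concealed-prolongation contrast.  Every experiment is a pure function of
its integer seed.

Problem sizes (sessions, replicates) are arguments with defaults chosen to
keep a full calibration run in the minutes range on one CPU; the
statistical assertions in the test-suite are stated against these sizes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import effect_stats
from .pipeline import AnalysisConfig, StudyResult, analyze_study
from .simulator import (
    DrugEffect,
    ScenarioConfig,
    concealed_prolongation_drug,
    moxifloxacin_like_drug,
    simulate_study,
)

log = logging.getLogger(__name__)

_PRIME = 1_000_003


def _child_seed(seed: int, i: int) -> int:
    return (seed * _PRIME + i) % (2 ** 31)


def simulate_and_analyze(scenario: ScenarioConfig,
                         models=("onestep",),
                         mode: str = "dqtc",
                         cfg: AnalysisConfig | None = None) -> StudyResult:
    study = simulate_study(scenario)
    return analyze_study(study.manifest, study.beats, models, mode, cfg)


# ---------------------------------------------------------------------------
# null behaviour of the hourly interval
# ---------------------------------------------------------------------------

def null_hour_rates(n_hours: int = 2000, seed: int = 0,
                    hours_per_study: int = 12,
                    n_animals: int = 4) -> dict:
    """Exceedance rates of the one-sided bound under a true null.

    Simulates vehicle-vs-vehicle crossover studies (zero drug effect) and,
    for every post-dose hour, the pooled one-step ΔQTc interval.  Reports
    the fraction of hours with lb > 0 (nominally 0.05), the fraction with
    lb >= 5 ms (the false-positive rate of the TQT rule) and the same
    rates for the animal-level (n = animals) interval.
    """
    pooled_lb0 = pooled_fp5 = animal_lb0 = 0
    got = 0
    n_studies = 0
    while got < n_hours:
        scenario = ScenarioConfig(
            study_id=f"null{n_studies}", n_animals=n_animals,
            session_hours=1.0 + hours_per_study, dose_time_h=1.0,
            seed=_child_seed(seed, n_studies), drug=None)
        res = simulate_and_analyze(scenario, models=("onestep",))
        effects = res.reports["onestep"].effects
        animal_effects = {e.hour_index: e for e in res.onestep_animal_effects}
        for e in effects:
            if got >= n_hours:
                break
            got += 1
            pooled_lb0 += e.lb > 0
            pooled_fp5 += e.lb >= 5.0
            ae = animal_effects.get(e.hour_index)
            if ae is not None:
                animal_lb0 += ae.lb > 0
        n_studies += 1
    return {
        "n_hours": got,
        "pooled_lb0_rate": pooled_lb0 / got,
        "pooled_fp5_rate": pooled_fp5 / got,
        "animal_lb0_rate": animal_lb0 / got,
    }


# ---------------------------------------------------------------------------
# recovery of an injected prolongation
# ---------------------------------------------------------------------------

def constant_prolongation_drug(dqt_ms: float = 10.0) -> DrugEffect:
    """A flat (step) QTc prolongation switched on at dosing."""
    return DrugEffect(dqt_max=dqt_ms, profile="constant", t_lag=0.0)


def recovery_experiment(n_reps: int = 150, seed: int = 0,
                        dqt_ms: float = 10.0,
                        plateau_hours: int = 4,
                        n_animals: int = 4) -> dict:
    """Mean recovered one-step ΔQTc under a constant injected effect.

    Each replicate is a crossover study whose treated sessions carry a
    flat ``dqt_ms`` prolongation; the recovered value per replicate is
    the mean pooled ΔQTc over the plateau hours.  Returns the grand mean,
    its spread across replicates and the per-replicate values.
    """
    per_rep = np.empty(n_reps)
    for i in range(n_reps):
        scenario = ScenarioConfig(
            study_id=f"rec{i}", n_animals=n_animals,
            session_hours=1.0 + plateau_hours, dose_time_h=1.0,
            seed=_child_seed(seed, i),
            drug=constant_prolongation_drug(dqt_ms))
        res = simulate_and_analyze(scenario, models=("onestep",))
        means = [e.mean for e in res.reports["onestep"].effects
                 if 1 <= e.hour_index <= plateau_hours]
        per_rep[i] = float(np.mean(means))
    return {
        "injected_ms": dqt_ms,
        "n_reps": n_reps,
        "grand_mean_ms": float(per_rep.mean()),
        "rep_sd_ms": float(per_rep.std(ddof=1)),
        "per_rep": per_rep,
    }


# ---------------------------------------------------------------------------
# LSD battery: one-step vs conventional sensitivity
# ---------------------------------------------------------------------------

def lsd_battery(n_studies: int = 12, seed: int = 0,
                n_animals: int = 4) -> pd.DataFrame:
    """Per-study LSD for all three models over a simulated battery.

    Vehicle sessions run a full 24 h (the conventional circadian fit
    requires the whole cycle); treated sessions cover dosing plus the
    6-h peak window.  Studies alternate between no-drug and a
    positive-control-like drug — the LSD is a property of the noise and
    the interval construction, not of the effect size.  Returns the
    :func:`~onestepqtc.effect_stats.lsd_summary` frame (medians row last).
    """
    per_study: dict[str, dict[str, float]] = {}
    for i in range(n_studies):
        drug = moxifloxacin_like_drug() if i % 2 else None
        scenario = ScenarioConfig(
            study_id=f"battery{i:02d}", n_animals=n_animals,
            session_hours=24.0, treated_session_hours=9.0,
            dose_time_h=2.0, seed=_child_seed(seed, i), drug=drug)
        res = simulate_and_analyze(
            scenario, models=("onestep", "linqthr", "logqtrr"))
        per_study[scenario.study_id] = {
            model: effect_stats.study_lsd(rep.effects)
            for model, rep in res.reports.items()
        }
    return effect_stats.lsd_summary(per_study)


# ---------------------------------------------------------------------------
# concealed prolongation contrast
# ---------------------------------------------------------------------------

def concealed_contrast(n_seeds: int = 40, seed: int = 0,
                       n_animals: int = 4) -> dict:
    """How often the one-step model reveals a concealed prolongation.

    The scenario injects +12 ms QT, +25 bpm HR and a steepened QT/HR
    slope.  For each seed the study is analyzed with both the one-step
    model and the vehicle-slope LinQTHR model; the contrast counts seeds
    where one-step classifies positive (lb >= 5 ms) while LinQTHR does
    not.
    """
    onestep_pos = linqthr_pos = contrast = 0
    for i in range(n_seeds):
        scenario = ScenarioConfig(
            study_id=f"concealed{i}", n_animals=n_animals,
            session_hours=24.0, treated_session_hours=9.0,
            dose_time_h=2.0, seed=_child_seed(seed, i),
            drug=concealed_prolongation_drug())
        res = simulate_and_analyze(scenario, models=("onestep", "linqthr"))
        os_pos = res.reports["onestep"].classification == "positive"
        lin_pos = res.reports["linqthr"].classification == "positive"
        onestep_pos += os_pos
        linqthr_pos += lin_pos
        contrast += os_pos and not lin_pos
    return {
        "n_seeds": n_seeds,
        "onestep_positive_rate": onestep_pos / n_seeds,
        "linqthr_positive_rate": linqthr_pos / n_seeds,
        "contrast_rate": contrast / n_seeds,
    }


def moxifloxacin_like_study(seed: int = 0, n_animals: int = 4) -> dict:
    """One positive-control-like study; peak-hour one-step bounds."""
    scenario = ScenarioConfig(
        study_id="moxi_like", n_animals=n_animals,
        session_hours=24.0, treated_session_hours=9.0,
        dose_time_h=2.0, seed=seed, drug=moxifloxacin_like_drug())
    res = simulate_and_analyze(
        scenario, models=("onestep", "linqthr", "logqtrr"))
    rep = res.reports["onestep"]
    return {
        "peak_hour": rep.peak_hour,
        "peak_mean_ms": rep.peak.mean,
        "peak_lb_ms": rep.peak.lb,
        "peak_ub_ms": rep.peak.ub,
        "classification": rep.classification,
        "max_hr_change_bpm": rep.max_hr_change,
        "result": res,
    }
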