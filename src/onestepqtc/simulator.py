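"""Synthetic beagle crossover telemetry with known ground truth.

The generator produces 24-h-style beat-to-beat (time, RR, QT) series with
the features the analysis pipeline depends on:

* a circadian heart-rate rhythm (24 h cosine) around ~80 bpm;
* minute-scale autonomic fluctuations, modelled as stationary
  mean-reverting (Ornstein-Uhlenbeck) processes acting on two channels:
  on heart rate (the within-hour HR spread the hourly QT/HR regressions
  need) and directly on the QT level, independent of rate — the residual
  QTc variability that no rate correction can remove, which the one-step
  model uses to mimic between-subject variability;
* a negative linear QT/HR relationship (QT shortens as HR rises);
* QT hysteresis: the QT "sees" a first-order-lagged heart rate with a
  time constant of tens of seconds, the reason QTc values are computed on
  5-min means in the first place;
* additive drug effects on QT level, heart rate and the QT/HR slope,
  following a one-compartment absorption/elimination (Bateman) time
  course normalized to unit peak, or a constant (step) profile for
  calibration experiments.

Default parameter values are this package's own choices, picked to mimic
published canine telemetry ranges; every one of them is configurable, and
all statistical guarantees in the test-suite are stated against the
injected truth, not against any particular animal.

A study is a four-animal crossover: each animal gets one vehicle and one
treated session sharing the animal's physiology but with independent
noise.  All randomness derives from a single integer seed through
numpy SeedSequence spawning, so regeneration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .telemetry_io import Pairing, SessionMeta, StudyManifest, write_beats, write_manifest

log = logging.getLogger(__name__)

HR_REF = 80.0     # bpm; generative reference point of the QT/HR line
HR_FLOOR = 30.0   # bpm
QT_FLOOR = 50.0   # ms


@dataclass
class AnimalParams:
    """Physiology of one simulated dog."""

    qt_ref: float = 250.0          # ms, QT at HR_REF
    beta_true: float = -0.5        # ms/bpm, QT/HR slope (<= 0 in dogs)
    hr_mean: float = 80.0          # bpm
    circadian_amp: float = 12.0    # bpm, 24-h cosine amplitude
    circadian_phase: float = 8.0   # h, time of circadian HR peak
    autonomic_sd: float = 8.0      # bpm, stationary sd of the OU process
    autonomic_tau: float = 600.0   # s, OU correlation time
    qt_autonomic_sd: float = 6.0   # ms, HR-independent autonomic QT sd
    qt_autonomic_tau: float = 600.0  # s, its correlation time
    qt_noise_sd: float = 2.0       # ms, per-beat measurement noise
    hysteresis_tau: float = 90.0   # s, QT-adaptation lag time constant

    def __post_init__(self):
        if self.beta_true > 0:
            raise ValueError("beta_true must be <= 0 (canine QT/HR slope)")
        if min(self.autonomic_sd, self.qt_autonomic_sd,
               self.qt_noise_sd) < 0:
            raise ValueError("noise sds must be >= 0")
        if min(self.autonomic_tau, self.qt_autonomic_tau,
               self.hysteresis_tau) <= 0:
            raise ValueError("time constants must be > 0")


@dataclass
class DrugEffect:
    """Additive drug effect with a PK-like time course.

    ``profile="bateman"`` uses (exp(-ke*tau) - exp(-ka*tau)) normalized to
    peak 1, tau = hours since dose minus t_lag; ``profile="constant"``
    switches the full effect on at t_lag (useful for calibration).
    """

    dqt_max: float = 0.0       # ms added to QT at peak
    dhr_max: float = 0.0       # bpm added to HR at peak
    dbeta_max: float = 0.0     # ms/bpm added to the QT/HR slope at peak
    t_lag: float = 0.25        # h
    ka: float = 2.0            # 1/h absorption
    ke: float = 0.35           # 1/h elimination
    profile: str = "bateman"

    def __post_init__(self):
        if self.profile not in ("bateman", "constant"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "bateman":
            if self.ka == self.ke:
                raise ValueError("ka must differ from ke (Bateman form)")
            if not (self.ka > self.ke > 0):
                raise ValueError("require ka > ke > 0")


def effect_profile(t_hours, drug: DrugEffect):
    """Fraction of the maximal effect at ``t_hours`` since dosing, in [0, 1]."""
    t = np.asarray(t_hours, dtype=float)
    tau = t - drug.t_lag
    if drug.profile == "constant":
        out = np.where(tau >= 0.0, 1.0, 0.0)
    else:
        ka, ke = drug.ka, drug.ke
        t_peak = np.log(ka / ke) / (ka - ke)
        norm = np.exp(-ke * t_peak) - np.exp(-ka * t_peak)
        tau_pos = np.maximum(tau, 0.0)
        out = np.where(
            tau >= 0.0,
            (np.exp(-ke * tau_pos) - np.exp(-ka * tau_pos)) / norm,
            0.0,
        )
    return float(out) if out.ndim == 0 else out


@dataclass
class BetweenAnimalSD:
    """Between-animal spread of the physiology parameters."""

    qt_ref: float = 8.0       # ms
    beta_true: float = 0.05   # ms/bpm
    hr_mean: float = 5.0      # bpm
    circadian_phase: float = 2.0  # h


@dataclass
class ScenarioConfig:
    """One simulated crossover study."""

    study_id: str = "sim"
    n_animals: int = 4
    session_hours: float = 24.0
    treated_session_hours: float | None = None  # default: same as vehicle
    dose_time_h: float = 2.0
    seed: int = 0
    animal: AnimalParams = field(default_factory=AnimalParams)
    between: BetweenAnimalSD = field(default_factory=BetweenAnimalSD)
    drug: DrugEffect | None = None

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        hours = [self.session_hours]
        if self.treated_session_hours is not None:
            hours.append(self.treated_session_hours)
        if min(hours) < self.dose_time_h + 1:
            raise ValueError("sessions must extend >= 1 h past dosing")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _first_order_lag(x: np.ndarray, tau_s: float) -> np.ndarray:
    """Exponential smoothing with time constant tau on a 1 Hz grid."""
    a = np.exp(-1.0 / tau_s)
    y, _ = lfilter([1.0 - a], [1.0, -a], x, zi=[a * x[0]])
    return y


def _ou_process(sd: float, tau_s: float, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean Ornstein-Uhlenbeck samples on a 1 Hz grid."""
    a = np.exp(-1.0 / tau_s)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -a], innov)


def simulate_hr_track(params: AnimalParams, n_seconds: int,
                      dose_time_s: float | None = None,
                      drug: DrugEffect | None = None,
                      seed=None) -> np.ndarray:
    """Per-second instantaneous heart rate over a session (1 Hz grid)."""
    rng = _as_rng(seed)
    t = np.arange(n_seconds, dtype=float)
    hr = params.hr_mean + params.circadian_amp * np.cos(
        2.0 * np.pi * (t / 3600.0 - params.circadian_phase) / 24.0)
    if params.autonomic_sd > 0:
        hr = hr + _ou_process(params.autonomic_sd, params.autonomic_tau,
                              n_seconds, rng)
    if drug is not None and dose_time_s is not None:
        hr = hr + drug.dhr_max * effect_profile((t - dose_time_s) / 3600.0,
                                                drug)
    return np.maximum(hr, HR_FLOOR)


def simulate_beats(hr_track: np.ndarray, params: AnimalParams,
                   dose_time_s: float | None = None,
                   drug: DrugEffect | None = None,
                   seed=None) -> pd.DataFrame:
    """Beat series from an instantaneous heart-rate track.

    Beat times come from integrating the instantaneous rate; per-beat RR
    is 60000 over the instantaneous HR at the beat time.  The QT of each
    beat responds to a first-order-lagged heart rate (hysteresis):

        QT = qt_ref + (beta_true + dbeta*profile) * (hr_lagged - 80)
             + dqt*profile + autonomic_qt + noise

    where ``autonomic_qt`` is the rate-independent autonomic OU component
    (sd ``qt_autonomic_sd``) and ``noise`` is white per-beat measurement
    noise (sd ``qt_noise_sd``).
    """
    rng = _as_rng(seed)
    hr_track = np.asarray(hr_track, dtype=float)
    t_grid = np.arange(len(hr_track), dtype=float)
    rate = hr_track / 60.0  # beats per second
    cum = np.concatenate(([0.0], np.cumsum((rate[:-1] + rate[1:]) / 2.0)))
    n_beats = int(np.floor(cum[-1]))
    if n_beats < 1:
        raise ValueError("track too short to contain a single beat")
    t_beat = np.interp(np.arange(1, n_beats + 1, dtype=float), cum, t_grid)
    hr_beat = np.interp(t_beat, t_grid, hr_track)
    rr = 60000.0 / hr_beat

    hr_eff = np.interp(t_beat, t_grid,
                       _first_order_lag(hr_track, params.hysteresis_tau))
    if drug is not None and dose_time_s is not None:
        p = effect_profile((t_beat - dose_time_s) / 3600.0, drug)
    else:
        p = 0.0
    beta_eff = params.beta_true + (drug.dbeta_max if drug else 0.0) * p
    qt = (params.qt_ref + beta_eff * (hr_eff - HR_REF)
          + (drug.dqt_max if drug else 0.0) * p)
    if params.qt_autonomic_sd > 0:
        qt_ou = _ou_process(params.qt_autonomic_sd, params.qt_autonomic_tau,
                            len(hr_track), rng)
        qt = qt + np.interp(t_beat, t_grid, qt_ou)
    if params.qt_noise_sd > 0:
        qt = qt + rng.normal(0.0, params.qt_noise_sd, n_beats)
    qt = np.maximum(qt, QT_FLOOR)
    return pd.DataFrame({"time_s": t_beat, "rr_ms": rr, "qt_ms": qt})


def _draw_animal(base: AnimalParams, sd: BetweenAnimalSD,
                 rng: np.random.Generator) -> AnimalParams:
    return dataclasses.replace(
        base,
        qt_ref=base.qt_ref + rng.normal(0.0, sd.qt_ref),
        beta_true=min(base.beta_true + rng.normal(0.0, sd.beta_true), -0.05),
        hr_mean=base.hr_mean + rng.normal(0.0, sd.hr_mean),
        circadian_phase=base.circadian_phase + rng.normal(0.0, sd.circadian_phase),
    )


@dataclass
class SimulatedStudy:
    manifest: StudyManifest
    beats: dict[str, pd.DataFrame]
    ground_truth: dict


def simulate_study(scenario: ScenarioConfig,
                   out_dir: str | os.PathLike | None = None,
                   ) -> SimulatedStudy:
    """Simulate a full crossover study; optionally write it to disk.

    Produces one vehicle and one treated session per animal (shared
    physiology, independent noise), a manifest readable by
    :mod:`onestepqtc.telemetry_io` and a ground-truth record of every
    injected parameter.  With ``out_dir`` set, beat CSVs, manifest.yaml
    and ground_truth.json are written there (byte-identical under a fixed
    seed).
    """
    root = np.random.SeedSequence(scenario.seed)
    children = root.spawn(1 + 2 * scenario.n_animals)
    param_rng = np.random.default_rng(children[0])

    dose_s = scenario.dose_time_h * 3600.0
    veh_secs = int(round(scenario.session_hours * 3600)) + 1
    trt_hours = (scenario.treated_session_hours
                 if scenario.treated_session_hours is not None
                 else scenario.session_hours)
    trt_secs = int(round(trt_hours * 3600)) + 1

    sessions: list[SessionMeta] = []
    pairing: list[Pairing] = []
    beats: dict[str, pd.DataFrame] = {}
    truth_animals = {}

    for i in range(scenario.n_animals):
        animal_id = f"dog{i + 1}"
        params = _draw_animal(scenario.animal, scenario.between, param_rng)
        truth_animals[animal_id] = dataclasses.asdict(params)
        for j, (role, drug, n_sec) in enumerate((
                ("vehicle", None, veh_secs),
                ("treated", scenario.drug, trt_secs))):
            session_id = f"{animal_id}_{role}"
            rng = np.random.default_rng(children[1 + 2 * i + j])
            track = simulate_hr_track(params, n_sec, dose_s, drug, rng)
            beats[session_id] = simulate_beats(track, params, dose_s, drug,
                                               rng)
            sessions.append(SessionMeta(
                animal_id=animal_id, session_id=session_id,
                treatment_label="vehicle" if role == "vehicle" else "drug",
                role=role, dose_time_s=dose_s,
                beats_path=f"{session_id}.csv",
            ))
        pairing.append(Pairing(animal_id=animal_id,
                               vehicle=f"{animal_id}_vehicle",
                               treated=f"{animal_id}_treated"))

    manifest = StudyManifest(study_id=scenario.study_id,
                             sessions=sessions, pairing=pairing)
    ground_truth = {
        "scenario": {
            "study_id": scenario.study_id,
            "n_animals": scenario.n_animals,
            "session_hours": scenario.session_hours,
            "treated_session_hours": trt_hours,
            "dose_time_h": scenario.dose_time_h,
            "seed": scenario.seed,
        },
        "animals": truth_animals,
        "drug": dataclasses.asdict(scenario.drug) if scenario.drug else None,
    }
    study = SimulatedStudy(manifest=manifest, beats=beats,
                           ground_truth=ground_truth)
    if out_dir is not None:
        _write_study(study, out_dir)
    return study


def _write_study(study: SimulatedStudy, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for sid, df in study.beats.items():
        write_beats(df, os.path.join(out_dir, f"{sid}.csv"))
    write_manifest(study.manifest, os.path.join(out_dir, "manifest.yaml"))
    with open(os.path.join(out_dir, "ground_truth.json"), "w",
              encoding="utf-8") as fh:
        json.dump(study.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote simulated study %s (%d sessions) to %s",
             study.manifest.study_id, len(study.beats), out_dir)


# -- ready-made scenarios ---------------------------------------------------

def moxifloxacin_like_drug() -> DrugEffect:
    """A positive-control-like hERG blocker: ~10 ms QTc rise, mild HR drop."""
    return DrugEffect(dqt_max=10.0, dhr_max=-5.0, dbeta_max=0.0,
                      t_lag=0.5, ka=1.5, ke=0.3)


def concealed_prolongation_drug() -> DrugEffect:
    """Prolongation concealed under fixed-slope correction.

    +12 ms QT effect with +25 bpm tachycardia and a steepened (more
    negative) QT/HR slope: the HR rise drags corrected QT down under a
    vehicle-period slope, masking the prolongation, while a slope
    estimated from the treated session itself recovers it.  Kinetics are
    slow enough that the effect plateaus over hours 2-5: a rapid rise
    would make the drug ramp itself the dominant within-hour QT/HR
    covariation during hour 1 and confound that hour's slope fit.
    """
    return DrugEffect(dqt_max=12.0, dhr_max=25.0, dbeta_max=-0.3,
                      t_lag=0.25, ka=1.0, ke=0.25)
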