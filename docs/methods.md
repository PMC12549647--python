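# Methods

## Data model and preprocessing

The ingestion unit is a session: one animal, one continuous recording,
one row per beat (`time_s` from session start, `rr_ms`, `qt_ms`).  A
study manifest lists the sessions and the per-animal vehicle/treated
crossover pairing, with each session's dosing time in seconds from its
own start; all later indexing is dose-relative, so the two sessions of a
pair align without wall clocks.

Beat-to-beat heart rate is `HR = 60000/RR` (bpm).  Plausibility limits
(defaults for beagle dogs: RR 300–2000 ms, QT 100–450 ms, and QT < RR)
drop artifact beats with per-reason counts; the defaults bracket canine
physiology generously and are configurable, since automated delineation
pipelines differ in what they let through.  Retained beats are averaged
over half-open 60 s bins (minute pairs) and 300 s bins (5-min windows),
anchored at session start; the per-beat HR is averaged (not 60000 over
the mean RR) because rate is defined beat to beat first.  A minute needs
30 beats and a window 100 beats to be usable — a 5-min window typically
holds ~250–400 canine beats, so 100 tolerates bradycardia without losing
windows.  Dose-relative hour *h* ≥ 1 covers `[dose+(h-1)·3600,
dose+h·3600)`; hour 0 is the baseline hour before dosing.  Dosing times
are expected on the 5-min grid (they are rounded to it with a warning
otherwise).

## Correction models

**Conventional (LogQTRR, LinQTHR).**  One slope per animal, fitted by
ordinary least squares to the vehicle session's minute pairs over the
circadian cycle (at least 600 minutes spanning ≥ 20 h; no fallback — an
unusable vehicle day is an error).  LogQTRR fits log10 QT on log10 RR
and corrects `QTc = QT·(RRref/RR)^beta` with RRref = 750 ms; LinQTHR
fits QT on HR and corrects `QTc = QT - beta·(HR - HRref)` with HRref =
80 bpm (the two reference values are the same point: 60000/750 = 80).
The base-10 logarithm is part of the model definition; a natural log
would rescale the exponent.  The vehicle slope is applied to **both**
sessions — deliberately, since this fixed-slope transfer is the defining
property of conventional individual corrections and the mechanism of
concealed prolongation.  Per-minute QTc is averaged per dose-relative
hour (≥ 30 minutes present), and the hourly per-animal treated-minus-
vehicle differences are the effect samples (interval across animals,
n = number of animals).

**One-step.**  The slope is re-estimated every hour from the session
being corrected: OLS of QT on HR over that hour's minute pairs (≥ 45 of
60 minutes, HR spread ≥ 1 bpm; hours failing the preconditions borrow
the session's median hourly slope and are flagged, which preserves the
12-value grid without inventing per-hour information).  Five-minute
windows are corrected with their hour's own slope.  Treated-session
slopes always come from treated-session data; correcting with the
relationship actually in force during treatment is the model's central
assumption and what reveals concealed prolongation.  The regression is
QT on HR (linear): the QT/HR relationship is close to linear in dogs,
and the hourly HR range is far too narrow for the log-log curvature
refinement to matter.

Single-delta samples are time-matched window differences within animal;
double-delta subtracts each session's baseline-hour mean (≥ 6 of the 12
baseline windows required).  Windows pool across animals per hour: 48
values for four complete animals.

## Hourly inference

Each usable hour (n ≥ 2 samples) gets `mean ± LSD` with
`LSD = t(0.95, n-1)·s/√n` — the one-sided 95% interval whose half-width
is the least significant difference, the smallest mean effect
distinguishable from zero under the study's conditions.  Classification
over the peak window (default hours 1–6, extendable to 24 for delayed
effects): positive if any lower bound ≥ 5 ms; negative at TQT criteria
if every upper bound < 10 ms; inconclusive otherwise.  The peak is the
hour with the largest mean (ties: earliest).  The maximum heart-rate
change is the signed time-matched hourly HR difference (mean across
animals) of largest magnitude in the same window.  No multiplicity
adjustment is applied across hours, matching TQT practice.  Per-hour
treated-vs-vehicle slope differences are tested with a paired two-sided
t test across animals; a zero-variance nonzero difference is reported as
p = 0 with a degeneracy flag rather than failing.

**Pseudo-replication, quantified.**  The pooled one-step interval
treats the 12 per-animal windows of an hour as independent samples.
They are not: the autonomic processes that generate their variability
have ~10-minute correlation times, spanning neighbouring windows.  The
package measures the consequence under a zero-effect simulation
(`scripts/acceptance.py`): the pooled interval's one-sided size is ~0.2
instead of the nominal 0.05, and the 5 ms rule fires in ~1% of null
hours instead of essentially never.  The same run shows the animal-level
interval (per-animal hour means, n = animals), which the package exposes
alongside the pooled one, is calibrated (size ≈ 0.05, no 5 ms false
positives).  The pooled interval is nevertheless the method: its
anti-conservatism against zero is the price of the sensitivity that
makes a 4-animal study workable at the 5 ms threshold, and decisions are
taken at that threshold — where the null false-positive rate remains at
the percent level — not against zero.  Reports round to 0.1 ms; the
machine-readable CSVs keep full precision.

## The telemetry generator

Per-second instantaneous heart rate:

    hr(t) = hr_mean + circadian_amp·cos(2π(t/3600 - phase)/24)
            + OU(autonomic_sd, autonomic_tau) + dhr_max·profile(t)

with the mean-reverting (Ornstein–Uhlenbeck) term giving the
minute-scale spread the hourly regressions need, floored at 30 bpm.
Beat times integrate the instantaneous rate; per-beat RR is 60000/hr at
the beat time.  QT responds to a first-order-lagged heart rate
(hysteresis, time constant `hysteresis_tau`):

    QT = qt_ref + (beta_true + dbeta_max·profile)·(hr_lag - 80)
         + dqt_max·profile + OU(qt_autonomic_sd, qt_autonomic_tau)
         + N(0, qt_noise_sd)

floored at 50 ms.  Drug profiles are Bateman
(`exp(-ke·τ) - exp(-ka·τ)`, normalized to unit peak, τ = hours since
dose minus `t_lag`) or a constant step for calibration.  A study draws
per-animal physiology once (between-animal sds on qt_ref, slope, mean
HR, phase) and simulates one vehicle and one treated session per animal
with independent noise; all randomness descends from one integer seed
through SeedSequence spawning, so regeneration is byte-identical.

Defaults (all configurable):

| parameter | default | why |
|---|---|---|
| `qt_ref` | 250 ms | canine QT at 80 bpm |
| `beta_true` | -0.5 ms/bpm | typical canine QT/HR slope (must be ≤ 0) |
| `hr_mean` | 80 bpm | circadian-average canine HR; also HRref |
| `circadian_amp`, `circadian_phase` | 12 bpm, 8 h | day/night HR swing |
| `autonomic_sd`, `autonomic_tau` | 8 bpm, 600 s | minute-scale HR variability feeding the slope fits |
| `qt_autonomic_sd`, `qt_autonomic_tau` | 6 ms, 600 s | rate-independent autonomic QT variability (see below) |
| `qt_noise_sd` | 2 ms | per-beat measurement noise |
| `hysteresis_tau` | 90 s | QT adaptation lag, the reason for 5-min windows |

The rate-independent QT component is what a rate correction cannot
remove, and its magnitude is pinned by the sensitivity figures the
method is known for: a pooled one-step LSD around 2 ms at n = 48 implies
a window-level delta sd near 8 ms, i.e. a per-session window sd near
6 ms — an OU with sd 6 ms and tau 600 s delivers that, and the same
process predicts across-animal hourly conventional deltas of ~5 ms,
i.e. conventional LSDs of 5–7 ms.  Both magnitudes are reproduced by the
simulated battery (medians ≈ 1.9 / 4.5–5 / 4.7–5 ms for one-step /
LinQTHR / LogQTRR), so the generator sits in the regime where the
one-step sensitivity advantage actually operates.

Two intrinsic consequences are worth knowing.  First, hysteresis
attenuates hourly slope estimates: with a 90 s lag over 600 s-correlated
HR fluctuations the fitted slope is ~0.83–0.88 of the generative one
(measured; the property tests bound it).  This is a property of any
regression of lagged QT on instantaneous HR, not an estimator bug — the
estimator is unbiased to < 0.02 ms/bpm when QT adapts instantly.
Second, the slow QT process makes individual hourly slopes noisy
(sd ≈ 0.25 ms/bpm per hour); where a drug also shifts heart rate far
from 80 bpm, slope noise multiplies into QTc noise, which is why
concealed-prolongation detection is probabilistic rather than certain.

**Ready-made scenarios.**  `moxifloxacin_like_drug()` (+10 ms QT, mild
HR decrease) behaves like a positive control: ~10 ms recovered at
plateau, pooled bounds clear of 5 ms.  `concealed_prolongation_drug()`
(+12 ms QT, +25 bpm HR, slope steepened by -0.3 ms/bpm, peak ~2 h)
produces the concealment contrast: the tachycardia, corrected with the
vehicle-period slope, drags apparent QTc down so LinQTHR stays below the
5 ms threshold, while per-hour own-session slopes recover the
prolongation.  The slope must *steepen* for concealment — a shallower
treated slope with tachycardia would over-correct and exaggerate, not
hide, the effect.  Its kinetics plateau over hours 2–5 because a very
fast rise makes the drug ramp the dominant within-hour QT/HR covariation
during hour 1 and confounds that hour's slope fit.

**What the generator does not emulate** — and hence what passing tests
do not certify about real data: activity and feeding bursts,
arrhythmias and ectopy, T-wave morphology and delineation error
structure, body-temperature drift, day-to-day physiology shifts between
sessions beyond the noise processes, rate-dependent (use-dependent)
channel block, and any exposure–response relationship (profiles are
effect-shaped, not concentration-shaped).  Calibration results transfer
to real telemetry only insofar as its residual QTc variability resembles
a ~6 ms, ~10-minute-scale stationary process.

## Numerical choices

Slopes use the centered closed form `Σ(x-x̄)y / Σ(x-x̄)²` (robust for
regressors far from zero and verified against the normal equations to
1e-9).  Regression preconditions (minimum points, minimum regressor
spread) turn degenerate fits into explicit fallbacks or errors instead
of numerical noise.  Ties in peak detection resolve to the earliest
hour.  Hours with fewer than two effect samples are unusable; a study
with no usable hour in the window raises rather than classifying.  Beat
tables store 3 decimals (sub-ms precision is below measurement noise);
round-trips are exact at that precision.

Calibration problem sizes used by the test-suite and acceptance script —
null calibration on 1200–2000 simulated hours, recovery on 120–150
4-animal replicates, a 16–20-study battery, 60–100 concealment seeds,
with 8–25 h sessions as each experiment requires — are the package's
own choices, sized so Monte-Carlo error is small against each check's
tolerance while a full run stays in the minutes range on one CPU.

## Known limitations

* The pooled interval's anti-conservatism against zero (above) means
  pooled lower bounds near zero should not be read as significance
  statements; the 5 ms decision threshold and the animal-level interval
  are the trustworthy readouts.
* Hourly slopes are noisy under realistic rate-independent QT
  variability; single-hour slope values should be interpreted through
  the paired per-hour test across animals, not individually.
* The double delta assumes a stable baseline hour; sessions without 6
  usable baseline windows are excluded from it per animal.
* Conventional-model results require a full circadian vehicle record
  (≥ 20 h); short sessions support only the one-step model.
* No exposure–response modelling and no proarrhythmia scoring beyond
  the 5/10 ms bounds.
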