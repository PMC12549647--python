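"""Beat-to-beat telemetry tables and study manifests.

The ingestion boundary of the package is a deliberately small set of
plain-text dialects:

* **Beat tables** are CSV files with the header ``time_s,rr_ms,qt_ms``:
  one row per beat, time in seconds from session start (not wall clock),
  RR and QT intervals in milliseconds, values stored to three decimals.
* **Study manifests** are single YAML mappings describing the sessions of
  a crossover study (animal, session, vehicle/treated role, dosing time in
  seconds from that session's start, beat-table path) and the per-animal
  vehicle/treated pairing.

Vendor acquisition formats are intentionally not parsed; converting to the
CSV dialect above is the caller's responsibility.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: canonical beat-table column order
BEAT_COLUMNS = ("time_s", "rr_ms", "qt_ms")

#: sessions must carry at least this much pre-dose data by default, so a
#: baseline hour exists for the double-delta analysis
MIN_PREDOSE_S = 3600.0

VALID_ROLES = ("vehicle", "treated")


class TelemetryFormatError(ValueError):
    """A beat table violates the documented CSV dialect."""


class ManifestError(ValueError):
    """A study manifest is malformed or internally inconsistent."""


# ---------------------------------------------------------------------------
# beat tables
# ---------------------------------------------------------------------------

def read_beats(path: str | os.PathLike) -> pd.DataFrame:
    """Read a beat-to-beat CSV table.

    Returns a DataFrame with columns ``time_s``, ``rr_ms``, ``qt_ms``
    sorted by time.  Raises :class:`TelemetryFormatError` when a required
    column is missing, when time is not strictly increasing, or when an
    RR/QT value is non-positive.  Beats with ``qt >= rr`` are
    physiologically implausible but only flagged (counted to the log),
    never dropped here — plausibility filtering is a separate,
    configurable step (:func:`onestepqtc.preprocess.filter_beats`).
    """
    df = pd.read_csv(path)
    for col in BEAT_COLUMNS:
        if col not in df.columns:
            raise TelemetryFormatError(
                f"{path}: missing required column {col!r} "
                f"(header must name {', '.join(BEAT_COLUMNS)})"
            )
    df = df.loc[:, list(BEAT_COLUMNS)].astype(float)

    t = df["time_s"].to_numpy()
    if len(t) and t[0] < 0:
        raise TelemetryFormatError(f"{path}: negative time at row 0 ({t[0]})")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        i = int(bad[0]) + 1
        raise TelemetryFormatError(
            f"{path}: time_s not strictly increasing at data row {i} "
            f"(t={t[i]!r} follows t={t[i - 1]!r})"
        )
    for col in ("rr_ms", "qt_ms"):
        vals = df[col].to_numpy()
        neg = np.nonzero(~(vals > 0))[0]
        if neg.size:
            raise TelemetryFormatError(
                f"{path}: non-positive {col} at data row {int(neg[0])}"
            )
    n_implausible = int((df["qt_ms"].to_numpy() >= df["rr_ms"].to_numpy()).sum())
    if n_implausible:
        log.warning("%s: %d beats with qt >= rr (flagged, not dropped)",
                    path, n_implausible)
    span = t[-1] - t[0] if len(t) else 0.0
    log.info("%s: read %d beats spanning %.1f s", path, len(df), span)
    return df


def write_beats(series: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a beat table in the canonical CSV dialect (3 decimals)."""
    if series is None or len(series) == 0:
        raise ValueError("refusing to write an empty beat series")
    for col in BEAT_COLUMNS:
        if col not in series.columns:
            raise TelemetryFormatError(f"series lacks column {col!r}")
    series.loc[:, list(BEAT_COLUMNS)].to_csv(
        path, index=False, float_format="%.3f"
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class SessionMeta:
    """One telemetry session of one animal."""

    animal_id: str
    session_id: str
    treatment_label: str
    role: str                      # "vehicle" or "treated"
    dose_time_s: float             # seconds from session start
    beats_path: str | None = None  # beat CSV, relative to the manifest


@dataclass
class Pairing:
    """Crossover pairing: one vehicle and one treated session, same animal."""

    animal_id: str
    vehicle: str
    treated: str


@dataclass
class StudyManifest:
    study_id: str
    sessions: list[SessionMeta] = field(default_factory=list)
    pairing: list[Pairing] = field(default_factory=list)

    def session(self, session_id: str) -> SessionMeta:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)

    def validate(self, min_predose_s: float = MIN_PREDOSE_S) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        by_id: dict[str, SessionMeta] = {}
        for s in self.sessions:
            if s.session_id in by_id:
                problems.append(f"duplicate session_id {s.session_id!r}")
            by_id[s.session_id] = s
            if s.role not in VALID_ROLES:
                problems.append(
                    f"session {s.session_id!r}: role {s.role!r} not in "
                    f"{VALID_ROLES}"
                )
            if s.dose_time_s < min_predose_s:
                problems.append(
                    f"session {s.session_id!r}: dose_time_s "
                    f"{s.dose_time_s} < required pre-dose span "
                    f"{min_predose_s}"
                )
        for p in self.pairing:
            for sid, role in ((p.vehicle, "vehicle"), (p.treated, "treated")):
                s = by_id.get(sid)
                if s is None:
                    problems.append(
                        f"pairing for {p.animal_id!r}: unknown session {sid!r}"
                    )
                    continue
                if s.animal_id != p.animal_id:
                    problems.append(
                        f"pairing for {p.animal_id!r}: session {sid!r} "
                        f"belongs to animal {s.animal_id!r}"
                    )
                if s.role != role:
                    problems.append(
                        f"pairing for {p.animal_id!r}: session {sid!r} has "
                        f"role {s.role!r}, expected {role!r}"
                    )
        return problems


def _as_mapping(obj, what: str) -> dict:
    if not isinstance(obj, dict):
        raise ManifestError(f"{what} must be a mapping, got {type(obj).__name__}")
    return obj


def read_manifest(path: str | os.PathLike,
                  min_predose_s: float = MIN_PREDOSE_S) -> StudyManifest:
    """Read and validate a study manifest (YAML mapping)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    raw = _as_mapping(raw, "manifest")
    try:
        sessions = [
            SessionMeta(
                animal_id=str(s["animal_id"]),
                session_id=str(s["session_id"]),
                treatment_label=str(s.get("treatment_label", s["session_id"])),
                role=str(s["role"]),
                dose_time_s=float(s["dose_time_s"]),
                beats_path=s.get("beats"),
            )
            for s in raw.get("sessions", [])
        ]
        pairing = [
            Pairing(
                animal_id=str(p["animal_id"]),
                vehicle=str(p["vehicle"]),
                treated=str(p["treated"]),
            )
            for p in raw.get("pairing", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ManifestError(f"{path}: malformed manifest entry: {exc!r}") from exc
    manifest = StudyManifest(
        study_id=str(raw.get("study_id", "study")),
        sessions=sessions,
        pairing=pairing,
    )
    problems = manifest.validate(min_predose_s=min_predose_s)
    if problems:
        raise ManifestError(
            f"{path}: invalid manifest:\n  " + "\n  ".join(problems)
        )
    log.info("%s: %d sessions, %d pairings", path, len(sessions), len(pairing))
    return manifest


def write_manifest(manifest: StudyManifest, path: str | os.PathLike) -> None:
    doc = {
        "study_id": manifest.study_id,
        "sessions": [
            {
                "animal_id": s.animal_id,
                "session_id": s.session_id,
                "treatment_label": s.treatment_label,
                "role": s.role,
                "dose_time_s": float(s.dose_time_s),
                **({"beats": s.beats_path} if s.beats_path else {}),
            }
            for s in manifest.sessions
        ],
        "pairing": [
            {"animal_id": p.animal_id, "vehicle": p.vehicle, "treated": p.treated}
            for p in manifest.pairing
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_study(manifest_path: str | os.PathLike,
               min_predose_s: float = MIN_PREDOSE_S,
               ) -> tuple[StudyManifest, dict[str, pd.DataFrame]]:
    """Read a manifest plus every beat table it references.

    Beat paths are resolved relative to the manifest's directory.
    Returns ``(manifest, {session_id: beat DataFrame})``.
    """
    manifest = read_manifest(manifest_path, min_predose_s=min_predose_s)
    base = os.path.dirname(os.fspath(manifest_path))
    beats: dict[str, pd.DataFrame] = {}
    for s in manifest.sessions:
        if s.beats_path is None:
            raise ManifestError(
                f"session {s.session_id!r} has no beat-table path"
            )
        beats[s.session_id] = read_beats(os.path.join(base, s.beats_path))
    return manifest, beats
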