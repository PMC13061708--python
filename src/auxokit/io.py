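"""Cohort CSV and keypoints JSON readers/writers.

Cohort schema (one row per measurement session, UTF-8, header mandatory,
'.' decimal separator)::

    athlete_id, sex, birth_date, obs_date, standing_height_cm,
    sitting_height_cm, weight_kg, source, mother_height_cm, father_height_cm

Dates are ISO 8601; parental heights may be empty. Reading is fail-soft:
malformed rows are collected as :class:`RowError` with their line number
and the rest of the file is still loaded; ``strict=True`` raises on the
first problem instead.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

import pandas as pd

from .core import (
    AthleteProfile,
    AuxoError,
    MeasurementSession,
    Sex,
    Source,
    decimal_age,
)
from .photogrammetry import CameraSetup, KeypointSet, Posture

__all__ = [
    "COHORT_COLUMNS",
    "RowError",
    "CohortData",
    "read_cohort",
    "write_cohort",
    "sessions_from_frame",
    "read_keypoints",
]

COHORT_COLUMNS = [
    "athlete_id",
    "sex",
    "birth_date",
    "obs_date",
    "standing_height_cm",
    "sitting_height_cm",
    "weight_kg",
    "source",
    "mother_height_cm",
    "father_height_cm",
]


class FormatError(AuxoError, ValueError):
    """The file does not conform to the cohort schema."""


@dataclass(frozen=True)
class RowError:
    """A row that violated the schema or a type invariant."""

    line: int  # 1-based line number in the file (header is line 1)
    athlete_id: Optional[str]
    message: str


@dataclass
class CohortData:
    """Typed view of a cohort file: profiles keyed by id + session rows."""

    profiles: Dict[str, AthleteProfile]
    sessions: pd.DataFrame
    errors: List[RowError] = field(default_factory=list)

    @property
    def n_athletes(self) -> int:
        return len(self.profiles)


def _parse_optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def read_cohort(path, *, strict: bool = False) -> CohortData:
    """Read and validate a cohort CSV.

    Row-level failures (bad dates, inconsistent measurements, conflicting
    profile fields for the same athlete) are collected with 1-based line
    numbers; ``strict=True`` raises on the first one.
    """
    frame = pd.read_csv(path, dtype={"athlete_id": str})
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"cohort file missing columns {sorted(missing)}")

    profiles: Dict[str, AthleteProfile] = {}
    rows: List[dict] = []
    errors: List[RowError] = []
    for i, row in frame.iterrows():
        line = int(i) + 2  # header is line 1
        athlete_id = row["athlete_id"]
        try:
            profile = AthleteProfile(
                athlete_id=athlete_id,
                sex=Sex(row["sex"]),
                birth_date=datetime.date.fromisoformat(str(row["birth_date"])),
                mother_height_cm=_parse_optional_float(row["mother_height_cm"]),
                father_height_cm=_parse_optional_float(row["father_height_cm"]),
            )
            obs_date = datetime.date.fromisoformat(str(row["obs_date"]))
            session = MeasurementSession(
                date=obs_date,
                standing_height_cm=float(row["standing_height_cm"]),
                sitting_height_cm=float(row["sitting_height_cm"]),
                weight_kg=float(row["weight_kg"]),
                source=Source(row["source"]),
            )
            decimal_age(profile.birth_date, obs_date)  # raises OrderingError
            if athlete_id in profiles and profiles[athlete_id] != profile:
                raise FormatError(
                    f"conflicting profile fields for athlete {athlete_id!r}"
                )
        except (AuxoError, ValueError) as exc:
            err = RowError(line=line, athlete_id=athlete_id, message=str(exc))
            if strict:
                raise FormatError(f"line {line}: {exc}") from exc
            errors.append(err)
            continue
        profiles.setdefault(athlete_id, profile)
        rows.append({c: row[c] for c in COHORT_COLUMNS})

    sessions = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return CohortData(profiles=profiles, sessions=sessions, errors=errors)


def write_cohort(
    profiles: Mapping[str, AthleteProfile], sessions: pd.DataFrame, path
) -> None:
    """Write a cohort CSV in the canonical column order."""
    frame = sessions.copy()
    for col in COHORT_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"sessions frame missing column {col!r}")
    frame[COHORT_COLUMNS].to_csv(path, index=False)


def sessions_from_frame(
    sessions: pd.DataFrame,
) -> Iterator[Tuple[str, MeasurementSession]]:
    """Yield (athlete_id, MeasurementSession) for each session row."""
    for _, row in sessions.iterrows():
        date = row["obs_date"]
        if not isinstance(date, datetime.date):
            date = datetime.date.fromisoformat(str(date))
        yield str(row["athlete_id"]), MeasurementSession(
            date=date,
            standing_height_cm=float(row["standing_height_cm"]),
            sitting_height_cm=float(row["sitting_height_cm"]),
            weight_kg=float(row["weight_kg"]),
            source=Source(row["source"]),
        )


def read_keypoints(path) -> List[Tuple[str, KeypointSet, CameraSetup]]:
    """Read a keypoints JSON file.

    Accepts either one object or a list of objects of the form::

        {"athlete_id": ..., "posture": "standing"|"sitting",
         "top_px": [x, y], "bottom_px": [x, y],
         "camera": {"focal_px": ..., "wall_distance_cm": ...,
                    "camera_height_cm": ..., "principal_point_px": [x, y],
                    "image_size_px": [w, h]}}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        raw = [raw]
    out = []
    for entry in raw:
        cam_raw = dict(entry["camera"])
        if "principal_point_px" in cam_raw:
            cam_raw["principal_point_px"] = tuple(cam_raw["principal_point_px"])
        if "image_size_px" in cam_raw:
            cam_raw["image_size_px"] = tuple(cam_raw["image_size_px"])
        cam = CameraSetup(**cam_raw)
        kp = KeypointSet(
            posture=Posture(entry["posture"]),
            top_px=tuple(entry["top_px"]),
            bottom_px=tuple(entry["bottom_px"]),
        )
        out.append((str(entry["athlete_id"]), kp, cam))
    return out
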