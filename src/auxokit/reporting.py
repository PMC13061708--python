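"""Individual and team report builders.

Mirrors the dashboard views a coach or clinician works from: one report
per athlete (assessment history ordered by date, latest status/timing and
recommendation) and one team roll-up (status/timing counts, distribution
summaries of maturity offset, PHV age and percent of adult height).

Batch processing is fail-soft by default: per-athlete failures are
collected into the batch error list and the rest of the cohort is still
reported; ``strict=True`` raises on the first failure. Internal precision
is full float; rendered tables round to 2 decimals at serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import AthleteProfile, AuxoError
from .io import CohortData, sessions_from_frame
from .maturation import (
    ClassificationConfig,
    MaturityAssessment,
    PAHCoefficientTable,
    assess,
)

__all__ = ["IndividualReport", "TeamReport", "BatchError", "build_reports"]


@dataclass(frozen=True)
class BatchError:
    athlete_id: str
    message: str


@dataclass
class IndividualReport:
    """Assessment history for one athlete, strictly ordered by date."""

    athlete_id: str
    history: List[MaturityAssessment]

    def __post_init__(self) -> None:
        self.history = sorted(self.history, key=lambda r: (r.date, r.source))

    @property
    def latest(self) -> MaturityAssessment:
        return self.history[-1]

    def to_dict(self) -> dict:
        return {
            "athlete_id": self.athlete_id,
            "latest": self.latest.to_dict(),
            "history": [r.to_dict() for r in self.history],
        }


@dataclass
class TeamReport:
    """Cohort-level status/timing counts and metric distributions."""

    team_id: str
    n_athletes: int
    status_counts: Dict[str, int]
    timing_counts: Dict[str, int]
    metric_summaries: Dict[str, Tuple[float, float]]  # metric -> (mean, sd)
    errors: List[BatchError] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "team_id": self.team_id,
            "n_athletes": self.n_athletes,
            "status_counts": dict(sorted(self.status_counts.items())),
            "timing_counts": dict(sorted(self.timing_counts.items())),
            "metric_summaries": {
                k: {"mean": round(v[0], 2), "sd": round(v[1], 2)}
                for k, v in sorted(self.metric_summaries.items())
            },
            "errors": [
                {"athlete_id": e.athlete_id, "message": e.message}
                for e in self.errors
            ],
        }


def _latest_per_athlete(report: IndividualReport) -> MaturityAssessment:
    """Representative assessment: latest date, expert arm preferred on ties."""
    last_date = report.history[-1].date
    same_day = [r for r in report.history if r.date == last_date]
    for r in same_day:
        if r.source == "expert":
            return r
    return same_day[-1]


def build_reports(
    cohort: CohortData,
    *,
    team_id: str = "team",
    cfg: Optional[ClassificationConfig] = None,
    table: Optional[PAHCoefficientTable] = None,
    strict: bool = False,
) -> Tuple[List[IndividualReport], TeamReport]:
    """Run the maturation pipeline over a cohort and aggregate.

    Returns one :class:`IndividualReport` per athlete (deterministically
    ordered by athlete_id) plus a :class:`TeamReport` whose status counts
    are the exact histogram of the athletes' representative statuses.
    """
    if not cohort.profiles:
        raise AuxoError("cohort is empty")
    cfg = cfg or ClassificationConfig()
    table = table or PAHCoefficientTable.load_default()

    histories: Dict[str, List[MaturityAssessment]] = {}
    errors: List[BatchError] = []
    for athlete_id, session in sessions_from_frame(cohort.sessions):
        profile = cohort.profiles.get(athlete_id)
        if profile is None:
            err = BatchError(athlete_id, "session without profile")
            if strict:
                raise AuxoError(err.message)
            errors.append(err)
            continue
        try:
            result = assess(profile, session, table=table, cfg=cfg, strict=strict)
        except AuxoError as exc:
            if strict:
                raise
            errors.append(BatchError(athlete_id, str(exc)))
            continue
        histories.setdefault(athlete_id, []).append(result)

    individuals = [
        IndividualReport(athlete_id=aid, history=hist)
        for aid, hist in sorted(histories.items())
    ]

    status_counts: Dict[str, int] = {}
    timing_counts: Dict[str, int] = {}
    metrics: Dict[str, List[float]] = {
        "maturity_offset_yr": [],
        "phv_age_yr": [],
        "percent_adult_height": [],
    }
    for rep in individuals:
        latest = _latest_per_athlete(rep)
        status_counts[latest.status.value] = (
            status_counts.get(latest.status.value, 0) + 1
        )
        if latest.timing is not None:
            timing_counts[latest.timing.value] = (
                timing_counts.get(latest.timing.value, 0) + 1
            )
        for name in metrics:
            value = getattr(latest, name)
            if value is not None:
                metrics[name].append(float(value))

    summaries = {
        name: (
            (float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
            if vals
            else (float("nan"), float("nan"))
        )
        for name, vals in metrics.items()
    }
    team = TeamReport(
        team_id=team_id,
        n_athletes=len(individuals),
        status_counts=status_counts,
        timing_counts=timing_counts,
        metric_summaries=summaries,
        errors=errors,
    )
    assert sum(status_counts.values()) == len(individuals)  # conservation
    return individuals, team


def reports_to_json(
    individuals: List[IndividualReport], team: TeamReport, path=None
) -> str:
    """Serialize the batch to one stable JSON document."""
    doc = {
        "team": team.to_dict(),
        "individuals": [r.to_dict() for r in individuals],
    }
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text
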