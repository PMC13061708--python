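"""Domain types, calendar arithmetic and derived anthropometrics.

Everything downstream (maturity offset, predicted adult height, agreement
statistics) operates on the three records defined here: an athlete profile
(sex, birth date, parental statures), a dated measurement session (standing
height, sitting height, weight, and which method produced it), and the
derived predictors (decimal age, leg length, midparent stature,
weight-by-height ratio) that the regression equations consume.

Units are fixed package-wide: lengths in cm, mass in kg, ages in decimal
years. Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Optional

#: Mean Gregorian year; makes decimal age deterministic and leap-year robust.
DAYS_PER_YEAR = 365.2425

PARENT_HEIGHT_RANGE_CM = (120.0, 220.0)


class AuxoError(Exception):
    """Base class for all package errors."""


class OrderingError(AuxoError, ValueError):
    """A date precedes another date it must follow."""


class MeasurementError(AuxoError, ValueError):
    """Anthropometric measurements are mutually inconsistent."""


class RangeError(AuxoError, ValueError):
    """An input falls outside a method's validated range."""


class InsufficientInputError(AuxoError, ValueError):
    """A required predictor is absent."""


class ConfigurationError(AuxoError, ValueError):
    """A configuration object is incomplete or inconsistent."""


class PairingError(AuxoError, ValueError):
    """An athlete lacks the paired sessions a comparison requires."""


class UndefinedStatisticError(AuxoError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Source(str, enum.Enum):
    """Which measurement arm produced a session."""

    EXPERT = "expert"
    APP = "app"


@dataclass(frozen=True)
class AthleteProfile:
    """Identity-free demographic record.

    ``athlete_id`` is an opaque caller-supplied key; no names or
    institutional identifiers are stored. Parental statures, when present,
    must be plausible adult heights (120-220 cm).
    """

    athlete_id: str
    sex: Sex
    birth_date: datetime.date
    mother_height_cm: Optional[float] = None
    father_height_cm: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        for label, h in (
            ("mother_height_cm", self.mother_height_cm),
            ("father_height_cm", self.father_height_cm),
        ):
            if h is not None:
                lo, hi = PARENT_HEIGHT_RANGE_CM
                if not (lo <= float(h) <= hi):
                    raise MeasurementError(
                        f"{label}={h} outside plausible adult range [{lo}, {hi}] cm"
                    )

    @property
    def midparent_height_cm(self) -> Optional[float]:
        """Unadjusted mean of the two parental statures; None if either is absent."""
        if self.mother_height_cm is None or self.father_height_cm is None:
            return None
        return (self.mother_height_cm + self.father_height_cm) / 2.0


@dataclass(frozen=True)
class MeasurementSession:
    """One dated anthropometric observation, tagged by measuring method."""

    date: datetime.date
    standing_height_cm: float
    sitting_height_cm: float
    weight_kg: float
    source: Source = Source.EXPERT

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        if not (0.0 < self.sitting_height_cm < self.standing_height_cm):
            raise MeasurementError(
                "require 0 < sitting height "
                f"({self.sitting_height_cm}) < standing height "
                f"({self.standing_height_cm})"
            )
        if self.weight_kg <= 0:
            raise MeasurementError(f"weight must be positive, got {self.weight_kg}")


@dataclass(frozen=True)
class DerivedAnthro:
    """Predictor set derived from a profile + session pair.

    ``weight_by_height_ratio`` is weight/stature x 100, the dimensionless
    ratio the maturity-offset regressions use. ``midparent_height_cm`` is
    None when either parental stature is missing, in which case predicted
    adult height is unavailable rather than imputed.
    """

    decimal_age_yr: float
    leg_length_cm: float
    midparent_height_cm: Optional[float]
    weight_by_height_ratio: float


def decimal_age(birth_date: datetime.date, obs_date: datetime.date) -> float:
    """Elapsed time from birth to observation in mean-Gregorian years.

    Computed as (days between dates) / 365.2425 at full precision.

    Raises
    ------
    OrderingError
        If ``obs_date`` precedes ``birth_date``.
    """
    if obs_date < birth_date:
        raise OrderingError(
            f"observation date {obs_date} precedes birth date {birth_date}"
        )
    return (obs_date - birth_date).days / DAYS_PER_YEAR


def derive_anthro(profile: AthleteProfile, session: MeasurementSession) -> DerivedAnthro:
    """Compute the derived predictors for one session.

    Leg length is standing minus sitting height (subischial leg length);
    the session invariants guarantee it is strictly positive.
    """
    age = decimal_age(profile.birth_date, session.date)
    leg = session.standing_height_cm - session.sitting_height_cm
    if leg <= 0:  # unreachable through a valid session; guard for raw inputs
        raise MeasurementError("sitting height must be below standing height")
    return DerivedAnthro(
        decimal_age_yr=age,
        leg_length_cm=leg,
        midparent_height_cm=profile.midparent_height_cm,
        weight_by_height_ratio=session.weight_kg / session.standing_height_cm * 100.0,
    )
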