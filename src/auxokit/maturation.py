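"""The assessment engine: maturity offset, PHV age, predicted adult height,
percent of adult height, and maturity status/timing classification.

Maturity offset (MO) is the predicted signed time in years from the moment
of measurement to peak height velocity (PHV); negative values mean the
athlete has not yet reached PHV. It is computed with the sex-specific
interaction-term regressions of Mirwald et al. (2002) on decimal age,
stature, sitting height, leg length and weight. PHV age is then the
identity ``decimal age - MO``.

Predicted adult height (PAH) follows the Khamis-Roche functional form:
a linear combination of current stature, weight and midparent stature with
coefficients looked up per sex at the nearest tabulated half-year age.
The packaged coefficient table is a clearly-labelled synthetic stand-in
with that structure (see its header and :mod:`auxokit` docs); callers can
supply their own transcription of the published table.

Status (pre-pubertal / pubertal / post-pubertal) is keyed to distance from
PHV via configurable MO thresholds; timing (early / average / late)
compares PHV age against sex-specific population norms.
"""

from __future__ import annotations

import datetime
import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

from .core import (
    AthleteProfile,
    ConfigurationError,
    DerivedAnthro,
    InsufficientInputError,
    MeasurementSession,
    RangeError,
    Sex,
    derive_anthro,
)

__all__ = [
    "Status",
    "Timing",
    "Recommendation",
    "ClassificationConfig",
    "PAHCoefficientTable",
    "MaturityAssessment",
    "maturity_offset",
    "phv_age",
    "predicted_adult_height",
    "percent_adult_height",
    "classify_status",
    "classify_timing",
    "recommend",
    "assess",
    "MO_VALIDATED_AGE_RANGE",
]

#: Age range (yr) over which the maturity-offset regressions were validated.
MO_VALIDATED_AGE_RANGE: Tuple[float, float] = (8.0, 18.0)


class Status(str, enum.Enum):
    PRE_PUBERTAL = "pre_pubertal"
    PUBERTAL = "pubertal"
    POST_PUBERTAL = "post_pubertal"


class Timing(str, enum.Enum):
    EARLY = "early"
    AVERAGE = "average"
    LATE = "late"


class Recommendation(str, enum.Enum):
    """Training-adjustment categories for the status x timing mapping.

    The shipped default mapping is documentation of the mechanism, not
    sports-science advice; deployments should configure their own table.
    """

    MONITOR_GROWTH_SPURT = "monitor_growth_spurt"
    REDUCE_LOAD = "reduce_load"
    STANDARD_PROGRESSION = "standard_progression"
    EMPHASIZE_RECOVERY = "emphasize_recovery"


_DEFAULT_RECOMMENDATIONS: Dict[Tuple[Status, Timing], Recommendation] = {
    (Status.PRE_PUBERTAL, Timing.EARLY): Recommendation.MONITOR_GROWTH_SPURT,
    (Status.PRE_PUBERTAL, Timing.AVERAGE): Recommendation.STANDARD_PROGRESSION,
    (Status.PRE_PUBERTAL, Timing.LATE): Recommendation.STANDARD_PROGRESSION,
    (Status.PUBERTAL, Timing.EARLY): Recommendation.REDUCE_LOAD,
    (Status.PUBERTAL, Timing.AVERAGE): Recommendation.MONITOR_GROWTH_SPURT,
    (Status.PUBERTAL, Timing.LATE): Recommendation.MONITOR_GROWTH_SPURT,
    (Status.POST_PUBERTAL, Timing.EARLY): Recommendation.EMPHASIZE_RECOVERY,
    (Status.POST_PUBERTAL, Timing.AVERAGE): Recommendation.STANDARD_PROGRESSION,
    (Status.POST_PUBERTAL, Timing.LATE): Recommendation.STANDARD_PROGRESSION,
}

#: PHV-age population norms (mean, SD) in years used for timing by default.
#: Conventional longitudinal-study values; configurable per deployment.
_DEFAULT_TIMING_NORMS: Dict[Sex, Tuple[float, float]] = {
    Sex.MALE: (13.8, 1.0),
    Sex.FEMALE: (11.8, 1.0),
}


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds and norms for status/timing classification.

    Status is a total function of MO: below ``pre_threshold_yr`` is
    pre-pubertal, above ``post_threshold_yr`` post-pubertal, and the closed
    band between them (boundaries included) pubertal. Timing bands PHV age
    at ``timing_band_sd`` population SDs around the sex-specific norm mean.
    """

    pre_threshold_yr: float = -1.0
    post_threshold_yr: float = 1.0
    timing_norms: Mapping[Sex, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TIMING_NORMS)
    )
    timing_band_sd: float = 1.0
    recommendations: Mapping[Tuple[Status, Timing], Recommendation] = field(
        default_factory=lambda: dict(_DEFAULT_RECOMMENDATIONS)
    )

    def __post_init__(self) -> None:
        if not self.pre_threshold_yr < self.post_threshold_yr:
            raise ConfigurationError(
                "pre_threshold_yr must be below post_threshold_yr"
            )
        for sex, (mean, sd) in self.timing_norms.items():
            if sd <= 0:
                raise ConfigurationError(f"timing norm SD for {sex} must be > 0")

    @classmethod
    def from_json(cls, path) -> "ClassificationConfig":
        """Load a config from JSON.

        Recognised keys: ``pre_threshold_yr``, ``post_threshold_yr``,
        ``timing_band_sd``, ``timing_norms`` ({sex: [mean, sd]}) and
        ``recommendations`` ({"status,timing": category}).
        """
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        kwargs: dict = {}
        for key in ("pre_threshold_yr", "post_threshold_yr", "timing_band_sd"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "timing_norms" in raw:
            kwargs["timing_norms"] = {
                Sex(s): (float(v[0]), float(v[1]))
                for s, v in raw["timing_norms"].items()
            }
        if "recommendations" in raw:
            kwargs["recommendations"] = {
                (Status(k.split(",")[0]), Timing(k.split(",")[1])): Recommendation(v)
                for k, v in raw["recommendations"].items()
            }
        return cls(**kwargs)


def _load_mo_coefficients() -> Dict[Sex, Dict[str, float]]:
    with resources.files("auxokit.data").joinpath(
        "maturity_offset_coefficients.json"
    ).open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        Sex(sex): {k: float(v) for k, v in raw[sex].items()}
        for sex in ("male", "female")
    }


_MO_COEFFS = _load_mo_coefficients()


def maturity_offset(
    sex: Sex,
    anthro: DerivedAnthro,
    session: MeasurementSession,
    *,
    age_policy: str = "warn",
    validated_range: Tuple[float, float] = MO_VALIDATED_AGE_RANGE,
) -> float:
    """Predicted years to/from peak height velocity (negative = pre-PHV).

    Evaluates the sex-specific interaction regression on leg length (LL),
    sitting height (SH), decimal age, weight and the weight/height x 100
    ratio::

        male:   -9.236 + 0.0002708*LL*SH - 0.001663*age*LL
                       + 0.007216*age*SH + 0.02292*(Wt/Ht*100)
        female: -9.376 + 0.0001882*LL*SH + 0.0022*age*LL
                       + 0.005841*age*SH - 0.002658*age*Wt
                       + 0.07693*(Wt/Ht*100)

    The female equation's age x weight term and its absence from the male
    equation are preserved exactly as published; no re-fitting.

    Parameters
    ----------
    age_policy : {"warn", "error", "ignore"}
        What to do when decimal age falls outside ``validated_range``
        (default [8, 18] yr): warn and compute best-effort, raise
        :class:`~auxokit.core.RangeError`, or compute silently.
    """
    sex = Sex(sex)
    age = anthro.decimal_age_yr
    lo, hi = validated_range
    if not (lo <= age <= hi):
        msg = (
            f"decimal age {age:.2f} yr outside the maturity-offset "
            f"validated range [{lo}, {hi}] yr"
        )
        if age_policy == "error":
            raise RangeError(msg)
        if age_policy == "warn":
            warnings.warn(msg, stacklevel=2)
        elif age_policy != "ignore":
            raise ConfigurationError(f"unknown age_policy {age_policy!r}")
    c = _MO_COEFFS[sex]
    ll = anthro.leg_length_cm
    sh = session.sitting_height_cm
    wt = session.weight_kg
    return (
        c["intercept"]
        + c["ll_x_sh"] * ll * sh
        + c["age_x_ll"] * age * ll
        + c["age_x_sh"] * age * sh
        + c["age_x_wt"] * age * wt
        + c["wt_by_ht"] * anthro.weight_by_height_ratio
    )


def phv_age(decimal_age_yr: float, mo: float) -> float:
    """Predicted age at peak height velocity: chronological age minus MO."""
    return decimal_age_yr - mo


class PAHCoefficientTable:
    """Per (sex, half-year age) coefficient rows for predicted adult height.

    Rows hold ``(b0, b1, b2, b3)`` for PAH = b0 + b1*stature + b2*weight
    + b3*midparent stature. Ages are tabulated on a half-year grid within
    [4.0, 17.5] yr and each (sex, age) key is unique.
    """

    AGE_RANGE = (4.0, 17.5)

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "age_yr", "b0", "b1", "b2", "b3"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"coefficient table missing columns {missing}")
        frame = frame.copy()
        frame["sex"] = frame["sex"].map(Sex)
        ages = frame["age_yr"].to_numpy(dtype=float)
        lo, hi = self.AGE_RANGE
        if ((ages * 2) % 1 != 0).any() or ages.min() < lo or ages.max() > hi:
            raise ConfigurationError(
                f"ages must sit on the half-year grid within [{lo}, {hi}]"
            )
        if frame.duplicated(["sex", "age_yr"]).any():
            raise ConfigurationError("duplicate (sex, age) coefficient rows")
        self._frame = frame.set_index(["sex", "age_yr"]).sort_index()

    @classmethod
    def load_default(cls) -> "PAHCoefficientTable":
        """Load the packaged synthetic stand-in table (see its header)."""
        with resources.files("auxokit.data").joinpath(
            "pah_coefficients_synthetic.csv"
        ).open("r", encoding="utf-8") as fh:
            frame = pd.read_csv(fh, comment="#")
        return cls(frame)

    @classmethod
    def from_csv(cls, path) -> "PAHCoefficientTable":
        return cls(pd.read_csv(path, comment="#"))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def lookup(
        self, sex: Sex, age_yr: float, *, interpolate: bool = False
    ) -> Tuple[float, float, float, float]:
        """Coefficient row for a sex at an age.

        Default behaviour mirrors the tabulated form of the method: the row
        at the *nearest* half-year grid point (ties round up). With
        ``interpolate=True`` the two bracketing rows are blended linearly.
        """
        sex = Sex(sex)
        lo, hi = self.AGE_RANGE
        if not (lo <= age_yr <= hi):
            raise RangeError(
                f"age {age_yr:.2f} yr outside PAH table range [{lo}, {hi}]"
            )
        sub = self._frame.loc[sex]
        if interpolate:
            import numpy as np

            grid = sub.index.to_numpy(dtype=float)
            vals = sub[["b0", "b1", "b2", "b3"]].to_numpy(dtype=float)
            return tuple(
                float(np.interp(age_yr, grid, vals[:, j])) for j in range(4)
            )
        grid_age = int(age_yr * 2 + 0.5) / 2  # nearest half year, ties up
        grid_age = min(max(grid_age, lo), hi)
        row = sub.loc[grid_age]
        return (float(row["b0"]), float(row["b1"]), float(row["b2"]), float(row["b3"]))


def predicted_adult_height(
    sex: Sex,
    anthro: DerivedAnthro,
    session: MeasurementSession,
    table: Optional[PAHCoefficientTable] = None,
    *,
    interpolate: bool = False,
) -> float:
    """Khamis-Roche-form adult stature forecast in cm.

    Raises
    ------
    InsufficientInputError
        If midparent stature is absent (one-parent profiles are not imputed).
    RangeError
        If decimal age falls outside the table's [4.0, 17.5] yr range.
    """
    if anthro.midparent_height_cm is None:
        raise InsufficientInputError(
            "predicted adult height requires both parental statures"
        )
    if table is None:
        table = PAHCoefficientTable.load_default()
    b0, b1, b2, b3 = table.lookup(
        Sex(sex), anthro.decimal_age_yr, interpolate=interpolate
    )
    return (
        b0
        + b1 * session.standing_height_cm
        + b2 * session.weight_kg
        + b3 * anthro.midparent_height_cm
    )


def percent_adult_height(current_cm: float, pah_cm: float) -> float:
    """Current stature as a percentage of predicted adult height."""
    if pah_cm <= 0:
        raise InsufficientInputError(f"PAH must be positive, got {pah_cm}")
    return 100.0 * current_cm / pah_cm


def classify_status(mo: float, cfg: Optional[ClassificationConfig] = None) -> Status:
    """Map maturity offset to pre-pubertal / pubertal / post-pubertal.

    The pubertal band is closed: both thresholds belong to pubertal.
    """
    cfg = cfg or ClassificationConfig()
    if mo < cfg.pre_threshold_yr:
        return Status.PRE_PUBERTAL
    if mo > cfg.post_threshold_yr:
        return Status.POST_PUBERTAL
    return Status.PUBERTAL


def classify_timing(
    phv_age_yr: float, sex: Sex, cfg: Optional[ClassificationConfig] = None
) -> Timing:
    """Early/average/late maturer relative to sex-specific PHV-age norms."""
    cfg = cfg or ClassificationConfig()
    sex = Sex(sex)
    if sex not in cfg.timing_norms:
        raise ConfigurationError(f"no timing norms configured for sex {sex.value}")
    mean, sd = cfg.timing_norms[sex]
    band = cfg.timing_band_sd * sd
    if phv_age_yr < mean - band:
        return Timing.EARLY
    if phv_age_yr > mean + band:
        return Timing.LATE
    return Timing.AVERAGE


def recommend(
    status: Status,
    timing: Timing,
    cfg: Optional[ClassificationConfig] = None,
) -> Recommendation:
    """Deterministic lookup in the configured status x timing mapping."""
    cfg = cfg or ClassificationConfig()
    key = (Status(status), Timing(timing))
    try:
        return cfg.recommendations[key]
    except KeyError:
        raise ConfigurationError(
            f"no recommendation configured for ({key[0].value}, {key[1].value})"
        ) from None


@dataclass(frozen=True)
class MaturityAssessment:
    """Derived maturation quantities for one athlete session.

    ``phv_age_yr == decimal_age_yr - maturity_offset_yr`` holds exactly.
    ``predicted_adult_height_cm``/``percent_adult_height``/``timing`` are
    None when their inputs are unavailable; ``flags`` records best-effort
    caveats (e.g. age outside a validated range) in non-strict mode.
    """

    athlete_id: str
    date: datetime.date
    source: str
    decimal_age_yr: float
    maturity_offset_yr: float
    phv_age_yr: float
    predicted_adult_height_cm: Optional[float]
    percent_adult_height: Optional[float]
    status: Status
    timing: Optional[Timing]
    recommendation: Optional[Recommendation]
    flags: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "athlete_id": self.athlete_id,
            "date": self.date.isoformat(),
            "source": self.source,
            "decimal_age_yr": self.decimal_age_yr,
            "maturity_offset_yr": self.maturity_offset_yr,
            "phv_age_yr": self.phv_age_yr,
            "predicted_adult_height_cm": self.predicted_adult_height_cm,
            "percent_adult_height": self.percent_adult_height,
            "status": self.status.value,
            "timing": self.timing.value if self.timing else None,
            "recommendation": (
                self.recommendation.value if self.recommendation else None
            ),
            "flags": list(self.flags),
        }


def assess(
    profile: AthleteProfile,
    session: MeasurementSession,
    *,
    table: Optional[PAHCoefficientTable] = None,
    cfg: Optional[ClassificationConfig] = None,
    strict: bool = False,
) -> MaturityAssessment:
    """Run the full assessment pipeline on one session.

    In non-strict mode, missing midparent stature or an age outside the
    PAH table leaves PAH/%PAH as None with a flag; strict mode raises.
    Maturity-offset age-range handling follows the same policy.
    """
    cfg = cfg or ClassificationConfig()
    anthro = derive_anthro(profile, session)
    flags = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        mo = maturity_offset(
            profile.sex,
            anthro,
            session,
            age_policy="error" if strict else "warn",
        )
        flags.extend(str(w.message) for w in caught)
    pa = phv_age(anthro.decimal_age_yr, mo)

    pah = pct = None
    try:
        pah = predicted_adult_height(profile.sex, anthro, session, table)
        pct = percent_adult_height(session.standing_height_cm, pah)
    except (InsufficientInputError, RangeError) as exc:
        if strict:
            raise
        flags.append(str(exc))

    status = classify_status(mo, cfg)
    try:
        timing = classify_timing(pa, profile.sex, cfg)
    except ConfigurationError:
        if strict:
            raise
        timing = None
        flags.append(f"no timing norms for sex {profile.sex.value}")
    rec = recommend(status, timing, cfg) if timing is not None else None

    return MaturityAssessment(
        athlete_id=profile.athlete_id,
        date=session.date,
        source=session.source.value,
        decimal_age_yr=anthro.decimal_age_yr,
        maturity_offset_yr=mo,
        phv_age_yr=pa,
        predicted_adult_height_cm=pah,
        percent_adult_height=pct,
        status=status,
        timing=timing,
        recommendation=rec,
        flags=tuple(flags),
    )
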