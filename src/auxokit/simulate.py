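"""Synthetic adolescent cohorts with known growth truths.

Every other module is testable without external data because this one
generates it: per-athlete Preece-Baines model 1 (PB1) growth curves with a
known true PHV age, cross-sectional measurement sessions observed by two
arms (an expert anthropometrist and an image-based app) under a stated
error model, and pinhole-camera keypoints consistent with the
photogrammetry module's geometry.

The default design emulates a validation cohort of 144 adolescent
athletes (76 males, 68 females) aged 10-17 years with one paired
expert/app session each. All randomness flows from one seed through a
`numpy.random.SeedSequence` spawn per athlete, so a given athlete's draw
does not depend on cohort size or ordering.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import (
    AthleteProfile,
    ConfigurationError,
    DAYS_PER_YEAR,
    Sex,
    Source,
)
from .photogrammetry import CameraSetup, KeypointSet, Posture

__all__ = [
    "GrowthCurveParams",
    "ErrorModel",
    "SyntheticCohort",
    "FramingError",
    "pb1_height",
    "pb1_velocity",
    "true_phv_age",
    "generate_cohort",
    "project_keypoints",
    "DEFAULT_PRIORS",
]


class FramingError(ConfigurationError):
    """The subject does not fit in the camera's field of view."""


@dataclass(frozen=True)
class GrowthCurveParams:
    """Preece-Baines model 1 parameters for one individual.

    h1 is adult stature, h_theta the stature at the timing parameter
    theta, and s0 < s1 the two rate constants (per year). theta sits near,
    but not exactly at, the age of peak height velocity.
    """

    h1: float
    h_theta: float
    s0: float
    s1: float
    theta: float

    def __post_init__(self) -> None:
        if not (0 < self.s0 < self.s1):
            raise ConfigurationError("require 0 < s0 < s1")
        if not self.h_theta < self.h1:
            raise ConfigurationError("require h_theta < h1")
        if not (10.0 <= self.theta <= 16.0):
            raise ConfigurationError("theta must lie in [10, 16] yr")


@dataclass(frozen=True)
class ErrorModel:
    """Measurement noise/bias of the two arms.

    Expert SD reflects a trained anthropometrist with a stadiometer;
    app SD and bias the image-based pipeline. Weight is measured with a
    scale in both arms, hence a single (small) weight SD.
    """

    expert_sd_cm: float = 0.3
    app_sd_cm: float = 0.8
    app_bias_cm: float = 0.0
    weight_sd_kg: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.expert_sd_cm, self.app_sd_cm, self.weight_sd_kg) < 0:
            raise ConfigurationError("error SDs must be non-negative")


def pb1_height(age_yr: float, p: GrowthCurveParams) -> float:
    """PB1 stature (cm) at an age:
    ``h1 - 2(h1 - h_theta) / (exp(s0(t - theta)) + exp(s1(t - theta)))``."""
    t = np.asarray(age_yr, dtype=float)
    d = t - p.theta
    h = p.h1 - 2.0 * (p.h1 - p.h_theta) / (np.exp(p.s0 * d) + np.exp(p.s1 * d))
    return float(h) if np.isscalar(age_yr) else h


def pb1_velocity(age_yr, p: GrowthCurveParams):
    """Analytic PB1 growth velocity dh/dt in cm/yr."""
    t = np.asarray(age_yr, dtype=float)
    d = t - p.theta
    e0, e1 = np.exp(p.s0 * d), np.exp(p.s1 * d)
    v = 2.0 * (p.h1 - p.h_theta) * (p.s0 * e0 + p.s1 * e1) / (e0 + e1) ** 2
    return float(v) if np.isscalar(age_yr) else v


def true_phv_age(
    p: GrowthCurveParams,
    *,
    grid: Optional[Tuple[float, float, float]] = None,
    tol_yr: float = 1e-4,
) -> float:
    """Age of the adolescent velocity peak, by dense grid + refinement.

    The analytic PB1 velocity is evaluated on a dense grid (default
    ``[theta - 4, theta + 6]`` in 0.01-yr steps; PB1 is not a valid infancy
    model, so the search window brackets the spurt rather than the whole
    lifespan). The interior local maximum nearest ``theta`` is then
    refined with bounded scalar minimisation to ``tol_yr`` (default
    1e-4 yr). Raises if the window contains no interior velocity maximum.
    """
    if grid is None:
        grid = (p.theta - 4.0, p.theta + 6.0, 0.01)
    lo, hi, step = grid
    ages = np.arange(lo, hi + step, step)
    v = pb1_velocity(ages, p)
    interior = np.nonzero(
        (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    )[0] + 1
    if interior.size == 0:
        raise ConfigurationError(
            "no interior velocity maximum on grid; curve has no spurt there"
        )
    i = int(interior[np.argmin(np.abs(ages[interior] - p.theta))])
    res = minimize_scalar(
        lambda t: -pb1_velocity(t, p),
        bounds=(ages[i - 1], ages[i + 1]),
        method="bounded",
        options={"xatol": tol_yr},
    )
    return float(res.x)


#: Sex-specific priors for the PB1 parameters and auxiliary models.
#: Means/SDs are loosely anthropometric synthetic defaults, not reference
#: data; they produce adult statures and spurt timings in realistic ranges.
DEFAULT_PRIORS: Dict[Sex, Dict[str, Tuple[float, float]]] = {
    Sex.MALE: {
        "h1": (178.0, 6.0),
        "drop": (15.0, 2.0),   # h1 - h_theta
        "s0": (0.11, 0.01),
        "s1": (1.10, 0.10),
        "theta": (14.0, 0.9),
    },
    Sex.FEMALE: {
        "h1": (165.0, 6.0),
        "drop": (13.0, 2.0),
        "s0": (0.11, 0.01),
        "s1": (1.10, 0.10),
        "theta": (12.0, 0.9),
    },
}

_THETA_BOUNDS = (10.0, 16.0)


def _sitting_fraction(age_yr: float) -> float:
    """Sitting-height share of stature: linear 0.53 at age 10 -> 0.52 at 18."""
    t = np.clip(age_yr, 10.0, 18.0)
    return 0.53 - 0.01 * (t - 10.0) / 8.0


@dataclass
class SyntheticCohort:
    """Simulated athletes with known truths and paired noisy sessions."""

    profiles: Dict[str, AthleteProfile]
    truths: pd.DataFrame      # athlete_id, sex, h1, h_theta, s0, s1, theta,
                              # true_phv_age_yr, true_height_cm, obs_age_yr
    sessions: pd.DataFrame    # cohort CSV schema, one expert + one app row
    seed: int = 0
    n_redraws: int = 0

    @property
    def n_athletes(self) -> int:
        return len(self.profiles)

    def write(self, cohort_path, truths_path=None) -> None:
        from .io import write_cohort

        write_cohort(self.profiles, self.sessions, cohort_path)
        if truths_path is not None:
            self.truths.to_csv(truths_path, index=False)


def _draw_params(
    sex: Sex, rng: np.random.Generator, priors
) -> GrowthCurveParams:
    pr = priors[sex]
    for _ in range(1000):
        h1 = rng.normal(*pr["h1"])
        drop = rng.normal(*pr["drop"])
        s0 = rng.normal(*pr["s0"])
        s1 = rng.normal(*pr["s1"])
        theta = float(np.clip(rng.normal(*pr["theta"]), *_THETA_BOUNDS))
        if drop > 5.0 and 0 < s0 < s1 and h1 > 120.0:
            return GrowthCurveParams(h1=h1, h_theta=h1 - drop, s0=s0, s1=s1, theta=theta)
    raise ConfigurationError("priors keep producing invalid growth curves")


def generate_cohort(
    n_male: int = 76,
    n_female: int = 68,
    age_range: Tuple[float, float] = (10.0, 17.0),
    priors: Optional[Dict] = None,
    err: Optional[ErrorModel] = None,
    *,
    n_waves: int = 1,
    wave_interval_yr: float = 0.5,
    assessment_date: datetime.date = datetime.date(2024, 6, 1),
) -> SyntheticCohort:
    """Simulate a paired-arm cross-sectional (or multi-wave) cohort.

    Per athlete: PB1 curve parameters drawn from sex-specific priors, an
    observation age uniform over ``age_range``, true standing height from
    the curve, sitting height as an age-dependent fraction of stature plus
    N(0, 0.5) cm individual variation, weight from a stature-indexed
    normal (BMI ~ N(16.5 + 0.45 (age - 10), 1.8), floored at 13), parental
    statures consistent with the athlete's adult stature, and one expert +
    one app session per wave (truth plus source-specific noise/bias).

    Sessions violating the type invariants (sitting >= standing,
    non-positive weight) are re-drawn; the count is recorded on the cohort.
    Regeneration with the same arguments is deterministic.
    """
    if n_male < 0 or n_female < 0:
        raise ConfigurationError("athlete counts must be non-negative")
    if not age_range[0] < age_range[1]:
        raise ConfigurationError("age_range must be increasing")
    priors = priors or DEFAULT_PRIORS
    err = err or ErrorModel()
    root = np.random.SeedSequence(err.seed)
    spawns = root.spawn(n_male + n_female)

    profiles: Dict[str, AthleteProfile] = {}
    truth_rows: List[dict] = []
    session_rows: List[dict] = []
    n_redraws = 0

    sexes = [Sex.MALE] * n_male + [Sex.FEMALE] * n_female
    for idx, (sex, ss) in enumerate(zip(sexes, spawns)):
        rng = np.random.default_rng(ss)
        athlete_id = f"ath{idx:04d}"
        p = _draw_params(sex, rng, priors)
        phv = true_phv_age(p)
        obs_age = float(rng.uniform(*age_range))

        # parental statures loosely consistent with the child's adult stature
        offset = 6.5 if sex is Sex.MALE else -6.5
        midparent = p.h1 - offset + rng.normal(0.0, 3.0)
        # reported to 0.1 cm like every other height in the schema
        mother = round(float(np.clip(midparent - 6.5 + rng.normal(0.0, 3.0), 140, 200)), 1)
        father = round(float(np.clip(midparent + 6.5 + rng.normal(0.0, 3.0), 150, 210)), 1)

        birth_date = assessment_date - datetime.timedelta(
            days=round(obs_age * DAYS_PER_YEAR)
        )
        profile = AthleteProfile(
            athlete_id=athlete_id,
            sex=sex,
            birth_date=birth_date,
            mother_height_cm=mother,
            father_height_cm=father,
        )
        profiles[athlete_id] = profile

        for wave in range(n_waves):
            wave_age = obs_age + wave * wave_interval_yr
            obs_date = assessment_date + datetime.timedelta(
                days=round(wave * wave_interval_yr * DAYS_PER_YEAR)
            )
            ht = pb1_height(wave_age, p)
            sit = ht * _sitting_fraction(wave_age) + rng.normal(0.0, 0.5)
            bmi = max(13.0, rng.normal(16.5 + 0.45 * (wave_age - 10.0), 1.8))
            wt = bmi * (ht / 100.0) ** 2

            for source in (Source.EXPERT, Source.APP):
                for _ in range(1000):
                    if source is Source.EXPERT:
                        m_ht = ht + rng.normal(0.0, err.expert_sd_cm)
                        m_sit = sit + rng.normal(0.0, err.expert_sd_cm)
                    else:
                        m_ht = ht + err.app_bias_cm + rng.normal(0.0, err.app_sd_cm)
                        m_sit = sit + err.app_bias_cm + rng.normal(0.0, err.app_sd_cm)
                    m_wt = wt + rng.normal(0.0, err.weight_sd_kg)
                    if 0.0 < m_sit < m_ht and m_wt > 0.0:
                        break
                    n_redraws += 1
                else:
                    raise ConfigurationError("cannot draw a valid session")
                session_rows.append(
                    {
                        "athlete_id": athlete_id,
                        "sex": sex.value,
                        "birth_date": birth_date.isoformat(),
                        "obs_date": obs_date.isoformat(),
                        "standing_height_cm": round(m_ht, 1),
                        "sitting_height_cm": round(m_sit, 1),
                        "weight_kg": round(m_wt, 1),
                        "source": source.value,
                        "mother_height_cm": mother,
                        "father_height_cm": father,
                    }
                )
            if wave == 0:
                truth_rows.append(
                    {
                        "athlete_id": athlete_id,
                        "sex": sex.value,
                        "h1": p.h1,
                        "h_theta": p.h_theta,
                        "s0": p.s0,
                        "s1": p.s1,
                        "theta": p.theta,
                        "true_phv_age_yr": phv,
                        "true_height_cm": ht,
                        "obs_age_yr": obs_age,
                    }
                )

    truths = pd.DataFrame(truth_rows)
    sessions = pd.DataFrame(session_rows)
    return SyntheticCohort(
        profiles=profiles,
        truths=truths,
        sessions=sessions,
        seed=err.seed,
        n_redraws=n_redraws,
    )


def project_keypoints(
    true_height_cm: float,
    cam: CameraSetup,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> KeypointSet:
    """Inverse of the photogrammetric stature estimate.

    Places the floor-contact keypoint at the pixel row whose world height
    is 0 and the head keypoint at the row imaging ``true_height_cm``, then
    adds optional Gaussian pixel noise. Raises :class:`FramingError` when
    either keypoint falls outside the image.
    """
    px, py = cam.principal_point_px
    scale = cam.focal_px / cam.wall_distance_cm  # px per cm at the wall
    floor_y = py + cam.camera_height_cm * scale
    head_y = py - (true_height_cm - cam.camera_height_cm) * scale
    _, img_h = cam.image_size_px
    if not (0 <= head_y <= img_h and 0 <= floor_y <= img_h):
        raise FramingError(
            f"subject of {true_height_cm} cm does not fit the "
            f"{cam.image_size_px} px frame"
        )
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        head_y += rng.normal(0.0, pixel_noise_sd)
        floor_y += rng.normal(0.0, pixel_noise_sd)
    return KeypointSet(
        posture=Posture.STANDING,
        top_px=(px, float(head_y)),
        bottom_px=(px, float(floor_y)),
    )
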