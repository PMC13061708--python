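"""Expert-vs-automated method agreement battery.

Implements the paired-comparison statistics used to validate an automated
anthropometric method against an expert reference: Bland-Altman style mean
difference with SD, the two-way mixed-effects absolute-agreement
single-measure intraclass correlation (ICC) with an F-based 95% CI,
absolute and relative technical error of measurement (TEM), and, for
categorical maturity classifications, a square cross-tabulation with
percent agreement and unweighted Cohen's kappa.

The user-facing surface follows the Model/Results idiom:
``MethodComparison(profiles, sessions).fit()`` returns an
:class:`AgreementResults` carrying per-metric estimates, their CIs, the
status cross-tab, and a ``summary()`` table. The low-level statistics are
plain functions usable on any paired arrays.

Conventions: differences are ``method_a - method_b`` with method A the
expert arm; the sample SD uses the n-1 denominator; TEM uses the classic
2n denominator; relative TEM is a percentage of the grand mean of both
methods' values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AthleteProfile,
    InsufficientInputError,
    PairingError,
    Source,
    UndefinedStatisticError,
)
from .maturation import (
    ClassificationConfig,
    MaturityAssessment,
    PAHCoefficientTable,
    assess,
)

__all__ = [
    "PairedContinuous",
    "CrossTab",
    "ContinuousAgreement",
    "AgreementResults",
    "MethodComparison",
    "mean_diff_sd",
    "tem",
    "icc_absolute_agreement",
    "crosstab_agreement",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedContinuous:
    """n ordered (method_a, method_b) pairs of one continuous metric."""

    a: np.ndarray
    b: np.ndarray
    metric_label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise InsufficientInputError("paired data must be equal-length 1-D arrays")
        if a.size < 2:
            raise InsufficientInputError("need at least 2 pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise InsufficientInputError("paired data must be complete and finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return int(self.a.size)


def mean_diff_sd(pairs: PairedContinuous) -> Tuple[float, float]:
    """Mean and sample SD (n-1) of the paired differences a - b."""
    d = pairs.a - pairs.b
    return float(d.mean()), float(d.std(ddof=1))


def tem(pairs: PairedContinuous) -> Tuple[float, Optional[float]]:
    """Absolute and relative technical error of measurement.

    TEM = sqrt(sum d_i^2 / 2n); relative TEM = 100 * TEM / grand mean of
    all 2n values. When the grand mean is zero the relative TEM is
    undefined and returned as None (with a warning); the absolute TEM is
    always returned.
    """
    d = pairs.a - pairs.b
    a_tem = float(np.sqrt((d ** 2).sum() / (2 * pairs.n)))
    grand = float(np.concatenate([pairs.a, pairs.b]).mean())
    if grand == 0.0:
        warnings.warn(
            "grand mean is zero; relative TEM undefined", stacklevel=2
        )
        return a_tem, None
    return a_tem, 100.0 * a_tem / grand


def _two_way_mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """Row (subject), column (rater) and residual mean squares of an n x k
    crossed two-way layout with one observation per cell."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute_agreement(
    pairs: PairedContinuous, alpha: float = 0.05
) -> Tuple[float, float, float]:
    """Two-way, absolute-agreement, single-measure ICC with F-based CI.

    From the two-way ANOVA decomposition with subject mean square MS_R,
    rater mean square MS_C and residual MS_E::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with k = 2 raters and n subjects. This is the form that penalises a
    systematic offset between methods (ICC(A,1) in McGraw & Wong's
    taxonomy, ICC(2,1) in Shrout & Fleiss'). The two-sided (1-alpha) CI
    uses the standard F-based construction with Satterthwaite degrees of
    freedom; bounds are clipped to [-1, 1].

    Raises
    ------
    InsufficientInputError
        Fewer than 3 subjects.
    UndefinedStatisticError
        Zero total variance (all 2n values identical).
    """
    n, k = pairs.n, 2
    if n < 3:
        raise InsufficientInputError("ICC needs at least 3 subjects")
    x = np.column_stack([pairs.a, pairs.b])
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    msr, msc, mse = _two_way_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # perfect agreement: degenerate CI
        return 1.0, 1.0, 1.0

    a_coef = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a_coef):
        return float(icc), 1.0, 1.0
    b_coef = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    num = (a_coef * msc + b_coef * mse) ** 2
    den = (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n * (msr - f_l * mse)
        / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_u * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    )
    lower, upper = float(np.clip(lower, -1, 1)), float(np.clip(upper, -1, 1))
    return float(icc), lower, upper


@dataclass(frozen=True)
class CrossTab:
    """Square contingency table of two methods' categorical labels.

    ``counts[i, j]`` is the number of subjects method A placed in category
    i and method B in category j; the diagonal is agreement.
    """

    categories: Tuple[str, ...]
    counts: np.ndarray
    n_total: int
    n_agree: int
    percent_agree: float
    kappa: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.categories), columns=list(self.categories)
        )

    def to_dict(self) -> dict:
        return {
            "categories": list(self.categories),
            "counts": self.counts.tolist(),
            "n_total": self.n_total,
            "n_agree": self.n_agree,
            "percent_agree": self.percent_agree,
            "kappa": self.kappa,
            "kappa_note": "derived from the cross-tab (unweighted Cohen's kappa)",
        }


def crosstab_agreement(
    labels_a: Sequence,
    labels_b: Sequence,
    categories: Sequence[str],
) -> CrossTab:
    """Cross-tabulate two label sequences and summarise their agreement.

    Percent agreement is the diagonal share; kappa is unweighted Cohen's
    kappa with chance agreement from the marginal products. Degenerate
    case: when the chance agreement p_e equals 1 (both methods constant in
    one category), kappa is defined as 1.0 under perfect agreement and 0.0
    otherwise, keeping "kappa = 1 iff perfect agreement" total.
    """
    la = [getattr(x, "value", x) for x in labels_a]
    lb = [getattr(x, "value", x) for x in labels_b]
    if len(la) != len(lb):
        raise InsufficientInputError("label sequences must have equal length")
    cats = [getattr(c, "value", c) for c in categories]
    index = {c: i for i, c in enumerate(cats)}
    m = len(cats)
    counts = np.zeros((m, m), dtype=int)
    for x, y in zip(la, lb):
        if x not in index or y not in index:
            raise InsufficientInputError(f"label {x!r}/{y!r} not in categories {cats}")
        counts[index[x], index[y]] += 1
    n_total = int(counts.sum())
    if n_total == 0:
        raise InsufficientInputError("no labels to tabulate")
    n_agree = int(np.trace(counts))
    p_o = n_agree / n_total
    row = counts.sum(axis=1) / n_total
    col = counts.sum(axis=0) / n_total
    p_e = float((row * col).sum())
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return CrossTab(
        categories=tuple(cats),
        counts=counts,
        n_total=n_total,
        n_agree=n_agree,
        percent_agree=100.0 * p_o,
        kappa=float(kappa),
    )


@dataclass(frozen=True)
class ContinuousAgreement:
    """Agreement summary of one continuous metric across the two arms."""

    metric: str
    n: int
    mean_diff: float
    sd_diff: float
    icc: float
    ci_low: float
    ci_high: float
    a_tem: float
    r_tem: Optional[float]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "a_tem": self.a_tem,
            "r_tem": self.r_tem,
        }


#: Metric selectors: assessment -> float. Stature/sitting come straight
#: from the session; the rest from the maturation pipeline.
METRIC_FIELDS = (
    "maturity_offset_yr",
    "phv_age_yr",
    "standing_height_cm",
    "sitting_height_cm",
)


@dataclass
class AgreementResults:
    """Fitted agreement battery: per-metric statistics + status cross-tab."""

    metrics: Dict[str, ContinuousAgreement]
    status_crosstab: Optional[CrossTab]
    n_subjects: int
    alpha: float
    metadata: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "alpha": self.alpha,
            "metadata": dict(sorted(self.metadata.items())),
            "metrics": {k: v.to_dict() for k, v in sorted(self.metrics.items())},
            "status_crosstab": (
                self.status_crosstab.to_dict() if self.status_crosstab else None
            ),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, path=None) -> pd.DataFrame:
        """Flat one-row-per-metric table (mean diff, SD, ICC, CI, TEMs)."""
        frame = pd.DataFrame(
            [m.to_dict() for _, m in sorted(self.metrics.items())],
            columns=[
                "metric", "n", "mean_diff", "sd_diff", "icc",
                "ci_low", "ci_high", "a_tem", "r_tem",
            ],
        )
        if path is not None:
            frame.to_csv(path, index=False, float_format="%.6f")
        return frame

    def summary(self) -> str:
        """Human-readable agreement table, rounded to 2 decimals."""
        lines = [
            "Method agreement (expert - app)",
            f"  subjects: {self.n_subjects}   "
            f"ICC: two-way mixed effects, absolute agreement, single measure "
            f"(F-based {100 * (1 - self.alpha):.0f}% CI)",
            "",
            f"  {'metric':<22}{'mean diff (SD)':>18}{'ICC (CI)':>24}"
            f"{'A.TEM':>8}{'R.TEM%':>8}",
        ]
        for name, m in sorted(self.metrics.items()):
            rtem = f"{m.r_tem:.2f}" if m.r_tem is not None else "n/a"
            lines.append(
                f"  {name:<22}"
                f"{m.mean_diff:>8.2f} ({m.sd_diff:.2f})"
                f"{m.icc:>10.3f} ({m.ci_low:.3f}-{m.ci_high:.3f})"
                f"{m.a_tem:>8.2f}{rtem:>8}"
            )
        if self.status_crosstab is not None:
            ct = self.status_crosstab
            lines += [
                "",
                "Maturity status cross-tabulation (rows expert, cols app):",
                ct.to_frame().to_string(),
                f"  agreement: {ct.n_agree}/{ct.n_total} "
                f"({ct.percent_agree:.1f}%), kappa {ct.kappa:.3f} (derived)",
            ]
        return "\n".join(lines)


class MethodComparison:
    """Paired expert-vs-app comparison over a measured cohort.

    Parameters
    ----------
    profiles : mapping of athlete_id -> AthleteProfile
    sessions : DataFrame in the cohort schema (one row per session) with
        both an expert- and an app-source row per athlete and date.
    metrics : which continuous metrics to compare (default
        :data:`METRIC_FIELDS`).
    """

    def __init__(
        self,
        profiles: Mapping[str, AthleteProfile],
        sessions: pd.DataFrame,
        *,
        metrics: Sequence[str] = METRIC_FIELDS,
        cfg: Optional[ClassificationConfig] = None,
        table: Optional[PAHCoefficientTable] = None,
        alpha: float = 0.05,
    ):
        self.profiles = dict(profiles)
        self.sessions = sessions.reset_index(drop=True)
        self.metrics = tuple(metrics)
        self.cfg = cfg or ClassificationConfig()
        self.table = table or PAHCoefficientTable.load_default()
        self.alpha = alpha

    def _paired_assessments(self) -> List[Tuple[tuple, tuple]]:
        """One ((assessment, session) expert, (assessment, session) app)
        pair per (athlete, date)."""
        from .io import sessions_from_frame  # local import avoids a cycle

        by_key: Dict[Tuple[str, object], Dict[str, tuple]] = {}
        for athlete_id, session in sessions_from_frame(self.sessions):
            if athlete_id not in self.profiles:
                raise PairingError(f"session for unknown athlete {athlete_id!r}")
            result = assess(
                self.profiles[athlete_id], session,
                table=self.table, cfg=self.cfg,
            )
            slot = by_key.setdefault((athlete_id, session.date), {})
            if session.source.value in slot:
                raise PairingError(
                    f"athlete {athlete_id!r} has duplicate "
                    f"{session.source.value} sessions on {session.date}"
                )
            slot[session.source.value] = (result, session)
        pairs = []
        for (athlete_id, date), slot in sorted(by_key.items()):
            missing = {Source.EXPERT.value, Source.APP.value} - set(slot)
            if missing:
                raise PairingError(
                    f"athlete {athlete_id!r} missing {sorted(missing)} "
                    f"session on {date}"
                )
            pairs.append((slot[Source.EXPERT.value], slot[Source.APP.value]))
        return pairs

    def fit(self) -> AgreementResults:
        """Compute every agreement statistic and return the results object."""
        paired = self._paired_assessments()
        if len(paired) < 3:
            raise InsufficientInputError(
                "agreement battery needs at least 3 paired subjects"
            )
        metrics: Dict[str, ContinuousAgreement] = {}
        for name in self.metrics:
            a = np.array([self._metric(*e, name) for e, _ in paired])
            b = np.array([self._metric(*p, name) for _, p in paired])
            pc = PairedContinuous(a, b, metric_label=name)
            md, sd = mean_diff_sd(pc)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a_tem, r_tem = tem(pc)
            try:
                icc, lo, hi = icc_absolute_agreement(pc, alpha=self.alpha)
            except UndefinedStatisticError:
                icc = lo = hi = float("nan")
            metrics[name] = ContinuousAgreement(
                metric=name, n=pc.n, mean_diff=md, sd_diff=sd,
                icc=icc, ci_low=lo, ci_high=hi, a_tem=a_tem, r_tem=r_tem,
            )
        ct = crosstab_agreement(
            [e[0].status for e, _ in paired],
            [p[0].status for _, p in paired],
            [s.value for s in self._status_order()],
        )
        return AgreementResults(
            metrics=metrics,
            status_crosstab=ct,
            n_subjects=len(paired),
            alpha=self.alpha,
            metadata={
                "icc_model": "two-way mixed effects, absolute agreement, single measure",
                "icc_ci": "F-based, two-sided",
                "difference_direction": "expert - app",
                "kappa": "unweighted Cohen's kappa, derived from the cross-tab",
            },
        )

    @staticmethod
    def _status_order():
        from .maturation import Status

        return (Status.PRE_PUBERTAL, Status.PUBERTAL, Status.POST_PUBERTAL)

    @staticmethod
    def _metric(result: MaturityAssessment, session, name: str) -> float:
        if hasattr(session, name):
            return float(getattr(session, name))
        value = getattr(result, name)
        if value is None:
            raise InsufficientInputError(
                f"metric {name!r} unavailable for athlete {result.athlete_id!r}"
            )
        return float(value)


def agreement_report(
    profiles: Mapping[str, AthleteProfile],
    sessions: pd.DataFrame,
    *,
    metrics: Sequence[str] = METRIC_FIELDS,
    cfg: Optional[ClassificationConfig] = None,
    table: Optional[PAHCoefficientTable] = None,
    alpha: float = 0.05,
) -> AgreementResults:
    """Convenience wrapper: build a :class:`MethodComparison` and fit it."""
    return MethodComparison(
        profiles, sessions, metrics=metrics, cfg=cfg, table=table, alpha=alpha
    ).fit()
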