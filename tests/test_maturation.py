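import datetime

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import auxokit as ak
from auxokit.core import (
    ConfigurationError,
    DerivedAnthro,
    InsufficientInputError,
    RangeError,
)
from conftest import make_fixture_table


def _anthro(age, ht, sh, wt, midparent=None):
    return DerivedAnthro(
        decimal_age_yr=age,
        leg_length_cm=ht - sh,
        midparent_height_cm=midparent,
        weight_by_height_ratio=wt / ht * 100.0,
    )


def _session(ht, sh, wt, source="expert"):
    return ak.MeasurementSession(datetime.date(2024, 6, 1), ht, sh, wt, source)


class TestMaturityOffset:
    def test_male_equation_term_by_term(self):
        """Independent hand evaluation of the male interaction regression."""
        age, ht, sh, wt = 13.0, 160.0, 82.0, 48.0
        ll = ht - sh
        expected = (
            -9.236
            + 0.0002708 * ll * sh
            - 0.001663 * age * ll
            + 0.007216 * age * sh
            + 0.02292 * (wt / ht * 100.0)
        )
        mo = ak.maturity_offset(ak.Sex.MALE, _anthro(age, ht, sh, wt), _session(ht, sh, wt))
        assert mo == pytest.approx(expected, abs=1e-12)
        assert mo == pytest.approx(-0.810, abs=5e-4)

    def test_female_equation_term_by_term(self):
        age, ht, sh, wt = 12.0, 155.0, 81.0, 45.0
        ll = ht - sh
        expected = (
            -9.376
            + 0.0001882 * ll * sh
            + 0.0022 * age * ll
            + 0.005841 * age * sh
            - 0.002658 * age * wt
            + 0.07693 * (wt / ht * 100.0)
        )
        mo = ak.maturity_offset(
            ak.Sex.FEMALE, _anthro(age, ht, sh, wt), _session(ht, sh, wt)
        )
        assert mo == pytest.approx(expected, abs=1e-12)
        assert mo == pytest.approx(0.181, abs=5e-4)

    def test_source_tag_does_not_affect_offset(self):
        anthro = _anthro(13.0, 160.0, 82.0, 48.0)
        mo_expert = ak.maturity_offset(
            ak.Sex.MALE, anthro, _session(160.0, 82.0, 48.0, "expert")
        )
        mo_app = ak.maturity_offset(
            ak.Sex.MALE, anthro, _session(160.0, 82.0, 48.0, "app")
        )
        assert mo_expert == mo_app

    def test_age_range_policy(self):
        anthro = _anthro(6.0, 120.0, 65.0, 22.0)
        session = _session(120.0, 65.0, 22.0)
        with pytest.warns(UserWarning):
            ak.maturity_offset(ak.Sex.MALE, anthro, session, age_policy="warn")
        with pytest.raises(RangeError):
            ak.maturity_offset(ak.Sex.MALE, anthro, session, age_policy="error")

    @given(eps=st.floats(1e-6, 0.5))
    def test_continuity_in_weight(self, eps):
        """MO responds to a weight perturbation by at most the coefficient
        bound |wt_by_ht| * 100/ht * eps (male: no age x weight term)."""
        age, ht, sh, wt = 13.0, 160.0, 82.0, 48.0
        base = ak.maturity_offset(ak.Sex.MALE, _anthro(age, ht, sh, wt), _session(ht, sh, wt))
        bumped = ak.maturity_offset(
            ak.Sex.MALE, _anthro(age, ht, sh, wt + eps), _session(ht, sh, wt + eps)
        )
        assert abs(bumped - base) <= 0.02292 * 100.0 / ht * eps + 1e-12


class TestPhvAge:
    @pytest.mark.parametrize(
        "age, mo, expected",
        [(13.0, -0.81, 13.81), (12.0, 0.0, 12.0), (15.5, 1.7, 13.8)],
    )
    def test_identity(self, age, mo, expected):
        assert ak.phv_age(age, mo) == pytest.approx(expected)

    @given(
        age=st.floats(8.0, 18.0),
        mo=st.floats(-6.0, 4.0),
    )
    def test_definition_and_roundtrip(self, age, mo):
        # the definition is exact; the float roundtrip holds to double precision
        assert ak.phv_age(age, mo) == age - mo
        assert ak.phv_age(age, mo) + mo == pytest.approx(age, abs=1e-12)


class TestPredictedAdultHeight:
    def test_fixture_row_arithmetic(self):
        table = make_fixture_table(b0=10.0, b1=0.9, b2=0.1, b3=0.1)
        anthro = _anthro(12.0, 150.0, 78.0, 40.0, midparent=170.0)
        pah = ak.predicted_adult_height(
            ak.Sex.MALE, anthro, _session(150.0, 78.0, 40.0), table
        )
        assert pah == pytest.approx(10.0 + 0.9 * 150 + 0.1 * 40 + 0.1 * 170)

    def test_real_table_matches_row_dot_product(self, pah_table):
        """Lookup + dot-product oracle against the packaged table row."""
        anthro = _anthro(13.2, 160.0, 82.0, 48.0, midparent=172.0)
        b0, b1, b2, b3 = pah_table.lookup(ak.Sex.MALE, 13.2)
        expected = b0 + b1 * 160.0 + b2 * 48.0 + b3 * 172.0
        pah = ak.predicted_adult_height(
            ak.Sex.MALE, anthro, _session(160.0, 82.0, 48.0), pah_table
        )
        assert pah == pytest.approx(expected, abs=1e-12)

    def test_nearest_half_year_lookup(self, pah_table):
        assert pah_table.lookup(ak.Sex.MALE, 13.2) == pah_table.lookup(ak.Sex.MALE, 13.0)
        assert pah_table.lookup(ak.Sex.MALE, 13.3) == pah_table.lookup(ak.Sex.MALE, 13.5)
        # tie rounds up
        assert pah_table.lookup(ak.Sex.MALE, 13.25) == pah_table.lookup(ak.Sex.MALE, 13.5)

    def test_age_outside_table_raises(self, pah_table):
        anthro = _anthro(3.0, 95.0, 55.0, 15.0, midparent=170.0)
        with pytest.raises(RangeError):
            ak.predicted_adult_height(
                ak.Sex.MALE, anthro, _session(95.0, 55.0, 15.0), pah_table
            )

    def test_missing_midparent_raises(self, pah_table):
        anthro = _anthro(12.0, 150.0, 78.0, 40.0, midparent=None)
        with pytest.raises(InsufficientInputError):
            ak.predicted_adult_height(
                ak.Sex.MALE, anthro, _session(150.0, 78.0, 40.0), pah_table
            )

    def test_monotone_in_midparent_wherever_b3_positive(self, pah_table):
        frame = pah_table.frame
        assert (frame["b3"] > 0).all()
        for mid_lo, mid_hi in [(160.0, 161.0), (170.0, 180.0)]:
            lo = ak.predicted_adult_height(
                ak.Sex.FEMALE,
                _anthro(11.0, 145.0, 77.0, 38.0, midparent=mid_lo),
                _session(145.0, 77.0, 38.0),
                pah_table,
            )
            hi = ak.predicted_adult_height(
                ak.Sex.FEMALE,
                _anthro(11.0, 145.0, 77.0, 38.0, midparent=mid_hi),
                _session(145.0, 77.0, 38.0),
                pah_table,
            )
            assert hi > lo


class TestPercentAdultHeight:
    @pytest.mark.parametrize(
        "cur, pah, expected",
        [(150.0, 166.0, 90.36), (166.0, 166.0, 100.0), (83.0, 166.0, 50.0)],
    )
    def test_values(self, cur, pah, expected):
        assert ak.percent_adult_height(cur, pah) == pytest.approx(expected, abs=5e-3)

    def test_nonpositive_pah_rejected(self):
        with pytest.raises(InsufficientInputError):
            ak.percent_adult_height(150.0, 0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "mo, expected",
        [
            (-1.5, ak.Status.PRE_PUBERTAL),
            (-1.0, ak.Status.PUBERTAL),  # boundary belongs to pubertal
            (1.0, ak.Status.PUBERTAL),
            (1.2, ak.Status.POST_PUBERTAL),
        ],
    )
    def test_status_thresholds(self, mo, expected, cfg):
        assert ak.classify_status(mo, cfg) is expected

    @given(mo=st.floats(-8.0, 8.0, allow_nan=False))
    def test_status_is_a_monotone_partition(self, mo, cfg):
        order = [ak.Status.PRE_PUBERTAL, ak.Status.PUBERTAL, ak.Status.POST_PUBERTAL]
        s = ak.classify_status(mo, cfg)
        assert s in order
        s_later = ak.classify_status(mo + 0.5, cfg)
        assert order.index(s_later) >= order.index(s)

    @pytest.mark.parametrize(
        "phv, expected",
        [(12.5, ak.Timing.EARLY), (13.8, ak.Timing.AVERAGE), (15.1, ak.Timing.LATE)],
    )
    def test_timing_bands(self, phv, expected):
        cfg = ak.ClassificationConfig(
            timing_norms={ak.Sex.MALE: (13.8, 1.0)}, timing_band_sd=1.0
        )
        assert ak.classify_timing(phv, ak.Sex.MALE, cfg) is expected

    def test_timing_missing_norms_raises(self):
        cfg = ak.ClassificationConfig(timing_norms={ak.Sex.MALE: (13.8, 1.0)})
        with pytest.raises(ConfigurationError):
            ak.classify_timing(12.0, ak.Sex.FEMALE, cfg)

    def test_recommendation_lookup(self, cfg):
        assert (
            ak.recommend(ak.Status.PUBERTAL, ak.Timing.EARLY, cfg)
            is ak.Recommendation.REDUCE_LOAD
        )
        assert (
            ak.recommend(ak.Status.PRE_PUBERTAL, ak.Timing.AVERAGE, cfg)
            is ak.Recommendation.STANDARD_PROGRESSION
        )

    def test_unmapped_pair_raises(self):
        truncated = ak.ClassificationConfig(
            recommendations={
                (ak.Status.PUBERTAL, ak.Timing.EARLY): ak.Recommendation.REDUCE_LOAD
            }
        )
        with pytest.raises(ConfigurationError):
            ak.recommend(ak.Status.POST_PUBERTAL, ak.Timing.LATE, truncated)


class TestAssessPipeline:
    def test_full_assessment(self, male_profile, male_session, pah_table, cfg):
        result = ak.assess(male_profile, male_session, table=pah_table, cfg=cfg)
        assert result.phv_age_yr == result.decimal_age_yr - result.maturity_offset_yr
        assert result.status is ak.Status.PUBERTAL
        assert 0 < result.percent_adult_height <= 110
        assert result.recommendation is not None

    def test_missing_parents_leaves_pah_absent(self, male_session):
        profile = ak.AthleteProfile("np", "male", datetime.date(2011, 6, 1))
        result = ak.assess(profile, male_session)
        assert result.predicted_adult_height_cm is None
        assert result.percent_adult_height is None
        assert any("parental" in f for f in result.flags)

    def test_strict_mode_raises_on_missing_parents(self, male_session):
        profile = ak.AthleteProfile("np", "male", datetime.date(2011, 6, 1))
        with pytest.raises(InsufficientInputError):
            ak.assess(profile, male_session, strict=True)
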