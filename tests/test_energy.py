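"""Unit and property tests for the deterministic energy-expenditure model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metcal import (
    ActivityProfile,
    AgeLookupError,
    BmrReferenceTable,
    DomainError,
    InconsistentProfileError,
    MetSet,
    NonWearEpisode,
    Participant,
    activity_energy,
    basal_metabolic_rate,
    body_surface_area,
    exercise_volume,
    mvpa_hours,
    questionnaire_tee,
    residual_light_hours,
    weekly_accelerometer_tee,
)
from metcal.energy import ImputationError
import pandas as pd


def _tee_fixed_point(participant, profile, mets, table):
    """Independent questionnaire-TEE oracle: iterate TEF = TEE/10 to a
    fixed point instead of using the closed form."""
    bmr = (
        table.standard_value(participant.sex, participant.age)
        * participant.weight**0.444
        * participant.height**0.663
        * 88.83
        * 24.0
        / 10000.0
    )
    weekly = list(profile.work_hours) + list(profile.offduty_hours)
    pa8 = 168.0 - 7.0 * profile.sleep_hours_per_day - sum(weekly)
    weekly.append(pa8)
    base = bmr * profile.sleep_hours_per_day / 24.0
    for h, m in zip(weekly, mets.met):
        base += participant.weight * 1.05 * (h / 7.0) * m
    tee = 0.0
    for _ in range(200):
        tee = base + 0.1 * tee
    return tee


@pytest.mark.parametrize(
    "weight,height,expected",
    [
        (1.0, 1.0, 88.83),  # unit inputs leave only the constant
        (53.0, 158.0, 14854.149715206635),
    ],
)
def test_body_surface_area_formula(weight, height, expected):
    assert body_surface_area(weight, height) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("weight,height", [(0.0, 158.0), (-1.0, 158.0), (53.0, 0.0)])
def test_body_surface_area_rejects_nonpositive(weight, height):
    with pytest.raises(DomainError):
        body_surface_area(weight, height)


def test_bsa_strictly_increasing():
    base = body_surface_area(53.0, 158.0)
    assert body_surface_area(54.0, 158.0) > base
    assert body_surface_area(53.0, 159.0) > base


def test_bmr_units_cancellation():
    """Standard value 1 kcal/m2/h with BSA forced to 10,000 cm2 gives
    exactly 24 kcal/day."""
    table = BmrReferenceTable(
        pd.DataFrame(
            {"sex": ["female"], "age_min": [18], "age_max": [99],
             "kcal_per_m2_per_h": [1.0]}
        )
    )
    # height solving 1^0.444 * h^0.663 * 88.83 = 10000 for weight 1 kg
    height = (10000.0 / 88.83) ** (1.0 / 0.663)
    p = Participant(id="u", age=40, weight=1.0, height=height)
    assert basal_metabolic_rate(p, table) == pytest.approx(24.0, rel=1e-12)


def test_bmr_worked_example(worked_participant, bmr_table):
    # standard value 32.7 (female, 40-49) x BSA(53, 158) x 24 / 10000
    assert basal_metabolic_rate(worked_participant, bmr_table) == pytest.approx(
        1165.7536696494167, rel=1e-12
    )


def test_bmr_age_outside_table_names_age(bmr_table):
    p = Participant(id="old", age=95, weight=50.0, height=150.0)
    with pytest.raises(AgeLookupError, match="95"):
        basal_metabolic_rate(p, bmr_table)


@pytest.mark.parametrize(
    "met,hours,weight,expected",
    [(1.0, 1.0, 1.0, 1.05), (3.0, 2.0, 50.0, 315.0), (0.0, 5.0, 60.0, 0.0)],
)
def test_activity_energy(met, hours, weight, expected):
    assert activity_energy(met, hours, weight) == pytest.approx(expected)


def test_activity_energy_rejects_negative():
    with pytest.raises(DomainError):
        activity_energy(-1.0, 1.0, 60.0)


def test_residual_light_hours_examples():
    base = ActivityProfile(8.0, (0, 0, 0, 0), (0, 0, 0))
    assert residual_light_hours(base) == pytest.approx(112.0)
    all_sleep = ActivityProfile(24.0, (0, 0, 0, 0), (0, 0, 0))
    assert residual_light_hours(all_sleep) == pytest.approx(0.0)


def test_residual_negative_raises_with_deficit():
    over = ActivityProfile(8.0, (60, 60, 0, 0), (0, 0, 0))
    with pytest.raises(InconsistentProfileError) as exc:
        residual_light_hours(over)
    assert exc.value.deficit_hours == pytest.approx(8.0)


def test_residual_clip_mode_warns_and_clips():
    over = ActivityProfile(8.0, (60, 60, 0, 0), (0, 0, 0))
    with pytest.warns(UserWarning, match="clipped"):
        assert residual_light_hours(over, clip=True) == 0.0


def test_profile_rejects_bad_inputs():
    with pytest.raises(DomainError):
        ActivityProfile(25.0, (0, 0, 0, 0), (0, 0, 0))
    with pytest.raises(DomainError):
        ActivityProfile(8.0, (-1, 0, 0, 0), (0, 0, 0))


def test_questionnaire_tee_worked_example(
    worked_participant, worked_profile, bmr_table
):
    tee = questionnaire_tee(
        worked_participant, worked_profile, MetSet.midrange(), bmr_table
    )
    assert tee == pytest.approx(2079.505389883139, rel=1e-12)


def test_questionnaire_tee_all_sleep_is_bmr_over_09(worked_participant, bmr_table):
    profile = ActivityProfile(24.0, (0, 0, 0, 0), (0, 0, 0))
    tee = questionnaire_tee(worked_participant, profile, MetSet.midrange(), bmr_table)
    bmr = basal_metabolic_rate(worked_participant, bmr_table)
    assert tee == pytest.approx(bmr / 0.9, rel=1e-12)


def test_tef_closure_on_cohort(random_cohort, bmr_table):
    """TEE - (sleep term + activity sum) == 0.1 x TEE to machine precision."""
    mets = MetSet.estimated()
    for rec in random_cohort:
        tee = questionnaire_tee(rec.participant, rec.profile, mets, bmr_table)
        bmr = basal_metabolic_rate(rec.participant, bmr_table)
        weekly = np.append(
            rec.profile.weekly_hours(), residual_light_hours(rec.profile)
        )
        s = bmr * rec.profile.sleep_hours_per_day / 24.0 + (
            rec.participant.weight * 1.05 * float(weekly @ mets.as_array()) / 7.0
        )
        assert tee - s == pytest.approx(0.1 * tee, rel=1e-9)


def test_time_conservation(random_cohort):
    for rec in random_cohort:
        pa8 = residual_light_hours(rec.profile)
        total = 7.0 * rec.profile.sleep_hours_per_day + float(
            rec.profile.weekly_hours().sum()
        ) + pa8
        assert total == pytest.approx(168.0, abs=1e-9)


def test_tee_matches_fixed_point_oracle(random_cohort, bmr_table):
    mets = MetSet.midrange()
    for rec in random_cohort:
        expected = _tee_fixed_point(rec.participant, rec.profile, mets, bmr_table)
        got = questionnaire_tee(rec.participant, rec.profile, mets, bmr_table)
        assert got == pytest.approx(expected, rel=1e-9)


@settings(max_examples=40, derandomize=True)
@given(
    idx=st.integers(min_value=0, max_value=7),
    bump=st.floats(min_value=0.01, max_value=3.0),
)
def test_tee_monotone_in_each_met(idx, bump, worked_participant, worked_profile):
    base_mets = MetSet.midrange()
    raised = list(base_mets.met)
    raised[idx] += bump
    tee0 = questionnaire_tee(worked_participant, worked_profile, base_mets)
    tee1 = questionnaire_tee(
        worked_participant, worked_profile, MetSet(met=tuple(raised))
    )
    assert tee1 >= tee0


def test_tee_monotone_in_weight(worked_profile, bmr_table):
    light = Participant(id="a", age=45, weight=50.0, height=158.0)
    heavy = Participant(id="b", age=45, weight=60.0, height=158.0)
    mets = MetSet.estimated()
    assert questionnaire_tee(heavy, worked_profile, mets, bmr_table) > (
        questionnaire_tee(light, worked_profile, mets, bmr_table)
    )


class TestMetSets:
    def test_midrange_values(self):
        assert MetSet.midrange().met == (1.3, 1.5, 2.5, 6.0, 3.0, 6.0, 10.0, 1.5)

    def test_estimated_values(self):
        assert MetSet.estimated().met == (1.2, 1.6, 1.8, 4.5, 2.4, 4.4, 9.4, 1.1)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            MetSet(met=(0.0,) * 8)


class TestMvpa:
    """The moderate category (2.4 METs calibrated, 3.0 midrange) flips in
    and out of MVPA depending on the MET set -- the mechanism behind the
    differing age trends."""

    profile = ActivityProfile(8.0, (0, 0, 0, 2.0), (1.0, 0, 0))

    def test_estimated_excludes_moderate(self):
        assert mvpa_hours(self.profile, MetSet.estimated()) == pytest.approx(2.0)

    def test_midrange_includes_moderate(self):
        assert mvpa_hours(self.profile, MetSet.midrange()) == pytest.approx(3.0)

    def test_empty_profile(self):
        empty = ActivityProfile(8.0, (0, 0, 0, 0), (0, 0, 0))
        assert mvpa_hours(empty, MetSet.estimated()) == 0.0

    def test_moderate_to_vigorous_shift(self):
        shifted = ActivityProfile(8.0, (0, 0, 0, 2.0), (0.0, 1.0, 0))
        est, mid = MetSet.estimated(), MetSet.midrange()
        assert mvpa_hours(shifted, est) > mvpa_hours(self.profile, est)
        assert mvpa_hours(shifted, mid) == mvpa_hours(self.profile, mid)

    def test_estimated_bounded_by_midrange_plus_walking(self, random_cohort):
        for rec in random_cohort:
            pa3 = rec.profile.work_hours[2]
            assert mvpa_hours(rec.profile, MetSet.estimated()) <= (
                mvpa_hours(rec.profile, MetSet.midrange()) + pa3 + 1e-12
            )

    def test_exercise_volume(self):
        assert exercise_volume(
            ActivityProfile(8.0, (0, 0, 0, 0), (1.0, 0, 0)), MetSet.midrange()
        ) == pytest.approx(3.0)
        assert exercise_volume(
            ActivityProfile(8.0, (0, 0, 0, 2.0), (0, 0, 0)), MetSet.estimated()
        ) == pytest.approx(9.0)


class TestWeeklyAccelerometerTee:
    def test_sleep_only_week_equals_bmr(self, worked_participant, bmr_table):
        tee = weekly_accelerometer_tee(
            [0.0] * 7, [[]] * 7, [24.0] * 7, worked_participant, bmr_table
        )
        assert tee == pytest.approx(
            basal_metabolic_rate(worked_participant, bmr_table), rel=1e-12
        )

    def test_bathing_rule(self, bmr_table):
        p = Participant(id="b", age=40, weight=60.0, height=160.0)
        base = weekly_accelerometer_tee(
            [500.0] * 7, [[]] * 7, [8.0] * 7, p, bmr_table
        )
        with_bath = weekly_accelerometer_tee(
            [500.0] * 7,
            [[NonWearEpisode(duration=1.0, kind="bathing")]] + [[]] * 6,
            [8.0] * 7,
            p,
            bmr_table,
        )
        # 1.5 METs x 1 h x 60 kg x 1.05 = 94.5 kcal spread over the 7-day mean
        assert with_bath - base == pytest.approx(94.5 / 7.0, rel=1e-12)

    def test_seven_day_fixture_matches_hand_computation(self, bmr_table):
        p = Participant(id="f", age=50, weight=60.0, height=165.0)
        device = [800.0, 850.0, 900.0, 750.0, 820.0, 780.0, 860.0]
        sleep = [7.0, 8.0, 7.5, 7.0, 6.5, 8.0, 7.0]
        episodes = [[] for _ in range(7)]
        episodes[0] = [NonWearEpisode(0.5, kind="bathing")]
        episodes[3] = [NonWearEpisode(1.0, kind="other-known", assigned_met=2.0)]
        got = weekly_accelerometer_tee(device, episodes, sleep, p, bmr_table)
        # independent day-by-day arithmetic
        bmr = 31.6 * (60.0**0.444 * 165.0**0.663 * 88.83) * 24.0 / 10000.0
        days = [d + bmr * s / 24.0 for d, s in zip(device, sleep)]
        days[0] += 1.5 * 0.5 * 60.0 * 1.05
        days[3] += 2.0 * 1.0 * 60.0 * 1.05
        assert got == pytest.approx(sum(days) / 7.0, rel=1e-12)

    def test_wrong_day_count_raises(self, worked_participant):
        with pytest.raises(DomainError):
            weekly_accelerometer_tee(
                [0.0] * 6, [[]] * 6, [8.0] * 6, worked_participant
            )

    def test_unknown_episode_without_met_raises(self, worked_participant):
        episodes = [[NonWearEpisode(1.0, kind="unknown")]] + [[]] * 6
        with pytest.raises(ImputationError):
            weekly_accelerometer_tee(
                [0.0] * 7, episodes, [8.0] * 7, worked_participant
            )


def test_participant_validation():
    with pytest.raises(DomainError):
        Participant(id="x", age=40, weight=None, height=158.0)
    with pytest.raises(DomainError):
        Participant(id="x", age=40, weight=-5.0, height=158.0)
    # missing anthropometry is representable when flagged
    p = Participant(id="x", age=40, has_anthropometry=False)
    assert p.weight is None
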