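"""Deterministic energy-expenditure model for a seven-category
physical-activity questionnaire.

The questionnaire records average weekly hours spent in four on-duty
activity categories (sitting, standing, walking, heavy work) and three
off-duty categories (moderate, vigorous, very vigorous exercise), plus
daily sleep from a diary.  Off-duty *light* activity is not asked; it is
the residual of the 168-hour week after sleep and the seven reported
categories.  Total energy expenditure (TEE, kcal/day) is assembled from

* a basal-metabolic-rate (BMR) sleep term, ``BMR x sleep/24``,
* activity energy ``weight x 1.05 x hours x MET`` summed over the eight
  categories (reported hours are weekly and divided by 7), and
* the thermic effect of food (TEF), defined as one tenth of TEE, so
  that ``TEE = (sleep term + activity sum) / 0.9`` exactly.

BMR uses a Japanese per-body-surface-area standard: ``BMR (kcal/day) =
standard value (kcal/m2/h) x BSA (cm2) x 24 / 10000`` with
``BSA (cm2) = weight^0.444 x height^0.663 x 88.83`` (weight in kg,
height in cm).  The standard values are a (sex, age-band) lookup table
shipped as replaceable CSV config data.

A reference TEE comes from a waist-worn uniaxial accelerometer worn for
7 consecutive days; non-wear episodes (bathing at 1.5 METs, or an
explicit compendium intensity) and sleep are imputed and added to the
device output, and the 7-day mean is the accelerometer TEE/day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

WEEK_HOURS = 168.0
KCAL_PER_MET_HOUR_KG = 1.05
TEF_FRACTION = 0.1
SLEEP_MET = 1.0
BATHING_MET = 1.5

WORK_CATEGORIES = ("sitting", "standing", "walking", "heavy_work")
OFFDUTY_CATEGORIES = ("moderate", "vigorous", "very_vigorous")
#: the eight intensity categories in questionnaire order; "light" is the
#: residual off-duty category (PA8), never reported directly.
CATEGORIES = WORK_CATEGORIES + OFFDUTY_CATEGORIES + ("light",)

#: midpoint intensities assigned to the questionnaire categories
MIDRANGE_METS = (1.3, 1.5, 2.5, 6.0, 3.0, 6.0, 10.0, 1.5)
#: posterior reference intensities from the accelerometer calibration
ESTIMATED_METS = (1.2, 1.6, 1.8, 4.5, 2.4, 4.4, 9.4, 1.1)
#: half-open intensity ranges [L, U) offered as questionnaire anchors
CATEGORY_BOUNDS = (
    (1.0, 1.5),
    (1.2, 2.0),
    (2.0, 4.0),
    (4.0, 8.0),
    (3.0, 5.0),
    (5.0, 8.0),
    (8.0, math.inf),
    (1.0, 2.0),
)


class DomainError(ValueError):
    """A physical quantity is outside its admissible domain."""


class ImputationError(DomainError):
    """A non-wear episode cannot be assigned an intensity."""


class InconsistentProfileError(DomainError):
    """Sleep plus reported activity exceed the 168-hour week."""

    def __init__(self, deficit_hours: float):
        self.deficit_hours = float(deficit_hours)
        super().__init__(
            "sleep plus reported activity exceed the 168 h week by "
            f"{self.deficit_hours:.4g} h"
        )


class AgeLookupError(LookupError):
    """Age falls outside the BMR reference table's bands."""


@dataclass(frozen=True)
class Participant:
    """Anthropometry and demographics of one survey participant.

    ``weight`` (kg) and ``height`` (cm) must be present and positive
    whenever ``has_anthropometry`` is true; records flagged as missing
    anthropometry or missing activity responses are carried only so the
    exclusion pipeline can count them.
    """

    id: str
    age: int
    sex: str = "female"
    weight: Optional[float] = None
    height: Optional[float] = None
    pregnant: bool = False
    has_anthropometry: bool = True
    has_activity_responses: bool = True

    def __post_init__(self) -> None:
        if self.has_anthropometry:
            if self.weight is None or self.height is None:
                raise DomainError(
                    f"participant {self.id!r}: anthropometry flagged present "
                    "but weight/height missing"
                )
            if self.weight <= 0 or self.height <= 0:
                raise DomainError(
                    f"participant {self.id!r}: weight and height must be > 0"
                )
        if int(self.age) < 18:
            raise DomainError(f"participant {self.id!r}: age {self.age} < 18")


@dataclass(frozen=True)
class ActivityProfile:
    """Weekly questionnaire hours plus daily sleep.

    ``work_hours`` are PA1..PA4 (sitting, standing, walking, heavy work)
    and ``offduty_hours`` are PA5..PA7 (moderate, vigorous, very
    vigorous), all in hours/week.  Sleep is hours/day.  The profile is
    *inconsistent* when ``7 x sleep + sum(PA1..7) > 168``; construction
    succeeds but :func:`residual_light_hours` then raises.
    """

    sleep_hours_per_day: float
    work_hours: tuple[float, float, float, float]
    offduty_hours: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.sleep_hours_per_day <= 24.0:
            raise DomainError(
                f"sleep {self.sleep_hours_per_day} h/day outside [0, 24]"
            )
        if len(self.work_hours) != 4 or len(self.offduty_hours) != 3:
            raise DomainError("expected 4 work and 3 off-duty categories")
        if any(h < 0 for h in self.work_hours + self.offduty_hours):
            raise DomainError("activity hours must be non-negative")

    def weekly_hours(self) -> np.ndarray:
        """Reported weekly hours for the seven categories PA1..PA7."""
        return np.asarray(self.work_hours + self.offduty_hours, dtype=float)

    @property
    def committed_hours(self) -> float:
        """Weekly hours accounted for by sleep and reported activity."""
        return 7.0 * self.sleep_hours_per_day + float(self.weekly_hours().sum())

    @property
    def is_consistent(self) -> bool:
        return self.committed_hours <= WEEK_HOURS + 1e-9


@dataclass(frozen=True)
class MetSet:
    """Eight MET intensity values with their questionnaire ranges.

    Order follows :data:`CATEGORIES`: the four work categories, the
    three off-duty exercise categories, then residual light activity.
    """

    met: tuple[float, ...]
    bounds: tuple[tuple[float, float], ...] = CATEGORY_BOUNDS
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(self.met) != 8:
            raise DomainError("a MetSet has exactly 8 intensities")
        if any(m <= 0 for m in self.met):
            raise DomainError("all MET values must be > 0")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.met, dtype=float)

    def __getitem__(self, i: int) -> float:
        return self.met[i]

    @classmethod
    def midrange(cls) -> "MetSet":
        """Midpoint intensities of the questionnaire anchor ranges."""
        return cls(met=MIDRANGE_METS, label="midrange")

    @classmethod
    def estimated(cls) -> "MetSet":
        """Accelerometer-calibrated posterior reference intensities."""
        return cls(met=ESTIMATED_METS, label="estimated")


class BmrReferenceTable:
    """Basal metabolic standard values (kcal/m2/h) by sex and age band.

    Bands must be contiguous and non-overlapping within each sex and all
    values strictly positive.  The shipped default approximates the
    Japanese per-BSA standard table and is replaceable via any CSV with
    columns ``sex, age_min, age_max, kcal_per_m2_per_h``.
    """

    _default: "BmrReferenceTable | None" = None

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "age_min", "age_max", "kcal_per_m2_per_h"}
        missing = required - set(frame.columns)
        if missing:
            raise DomainError(f"BMR table missing columns: {sorted(missing)}")
        if (frame["kcal_per_m2_per_h"] <= 0).any():
            raise DomainError("BMR standard values must be > 0")
        self._rows: dict[str, list[tuple[int, int, float]]] = {}
        for sex, grp in frame.groupby("sex"):
            grp = grp.sort_values("age_min")
            bands = list(
                zip(
                    grp["age_min"].astype(int),
                    grp["age_max"].astype(int),
                    grp["kcal_per_m2_per_h"].astype(float),
                )
            )
            for (lo, hi, _) in bands:
                if hi < lo:
                    raise DomainError(f"empty age band [{lo}, {hi}]")
            for (_, hi_prev, _), (lo_next, _, _) in zip(bands, bands[1:]):
                if lo_next != hi_prev + 1:
                    raise DomainError(
                        f"age bands not contiguous at {hi_prev}/{lo_next}"
                    )
            self._rows[str(sex)] = bands

    @classmethod
    def from_csv(cls, path) -> "BmrReferenceTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "BmrReferenceTable":
        if cls._default is None:
            with resources.files("metcal.data").joinpath(
                "bmr_reference.csv"
            ).open("r") as fh:
                cls._default = cls(pd.read_csv(fh))
        return cls._default

    def standard_value(self, sex: str, age: int) -> float:
        """kcal/m2/h for the band containing ``age``; raises otherwise."""
        bands = self._rows.get(sex)
        if bands is None:
            raise AgeLookupError(f"no BMR reference values for sex {sex!r}")
        for lo, hi, value in bands:
            if lo <= age <= hi:
                return value
        raise AgeLookupError(
            f"age {age} outside BMR reference bands "
            f"[{bands[0][0]}, {bands[-1][1]}] for sex {sex!r}"
        )


@dataclass(frozen=True)
class NonWearEpisode:
    """A period when the accelerometer was off, with an imputed intensity.

    Bathing is always 1.5 METs.  ``other-known`` episodes carry a
    compendium-style intensity supplied by the caller; ``unknown``
    episodes without one raise :class:`ImputationError` at use.
    """

    duration: float  # hours
    kind: str = "other-known"  # bathing | other-known | unknown
    assigned_met: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise DomainError("episode duration must be >= 0")
        if self.kind == "bathing":
            object.__setattr__(self, "assigned_met", BATHING_MET)
        if self.assigned_met is not None and self.assigned_met <= 0:
            raise DomainError("assigned MET must be > 0")

    @property
    def met(self) -> float:
        if self.assigned_met is None:
            raise ImputationError(
                f"non-wear episode of kind {self.kind!r} has no assigned MET"
            )
        return self.assigned_met


@dataclass(frozen=True)
class ValidationRecord:
    """One calibration observation: a participant's questionnaire profile
    paired with their 7-day mean accelerometer TEE (kcal/day)."""

    participant: Participant
    profile: ActivityProfile
    accelerometer_tee: float


def body_surface_area(weight: float, height: float) -> float:
    """Body surface area in cm2 from weight (kg) and height (cm).

    ``BSA = weight^0.444 x height^0.663 x 88.83``.
    """
    if weight <= 0 or height <= 0:
        raise DomainError("weight and height must be > 0")
    return weight**0.444 * height**0.663 * 88.83


def basal_metabolic_rate(
    participant: Participant, table: Optional[BmrReferenceTable] = None
) -> float:
    """BMR in kcal/day: standard value (kcal/m2/h) x BSA (cm2) x 24 / 10000."""
    table = table or BmrReferenceTable.default()
    if not participant.has_anthropometry:
        raise DomainError(
            f"participant {participant.id!r} lacks anthropometry"
        )
    standard = table.standard_value(participant.sex, int(participant.age))
    bsa = body_surface_area(participant.weight, participant.height)
    return standard * bsa * 24.0 / 10000.0


def activity_energy(met: float, hours: float, weight: float) -> float:
    """Energy of one activity bout: ``MET x hours x weight x 1.05`` kcal."""
    if met < 0 or hours < 0 or weight < 0:
        raise DomainError("MET, hours and weight must be >= 0")
    return met * hours * weight * KCAL_PER_MET_HOUR_KG


def residual_light_hours(profile: ActivityProfile, clip: bool = False) -> float:
    """Residual off-duty light-activity time PA8 in hours/week.

    ``168 - 7 x sleep - sum(PA1..7)``.  A negative residual raises
    :class:`InconsistentProfileError` unless ``clip`` is set, in which
    case it is clipped to zero with a warning (messy survey data mode).
    """
    residual = WEEK_HOURS - profile.committed_hours
    if residual < -1e-9:
        if clip:
            warnings.warn(
                f"profile over-commits the week by {-residual:.4g} h; "
                "residual light time clipped to 0",
                stacklevel=2,
            )
            return 0.0
        raise InconsistentProfileError(-residual)
    return max(residual, 0.0)


def questionnaire_tee(
    participant: Participant,
    profile: ActivityProfile,
    mets: MetSet,
    table: Optional[BmrReferenceTable] = None,
    clip_residual: bool = False,
) -> float:
    """Questionnaire TEE in kcal/day.

    ``TEE = BMR x sleep/24 + TEF + sum_i weight x 1.05 x PAi x METi``
    with weekly PA divided by 7 and TEF = TEE/10, solved in closed form
    as ``TEE = S / 0.9`` where S is the sleep term plus the activity sum.
    """
    bmr = basal_metabolic_rate(participant, table)
    pa8 = residual_light_hours(profile, clip=clip_residual)
    weekly = np.append(profile.weekly_hours(), pa8)
    daily_met_hours = float(weekly @ mets.as_array()) / 7.0
    s = (
        bmr * profile.sleep_hours_per_day / 24.0
        + participant.weight * KCAL_PER_MET_HOUR_KG * daily_met_hours
    )
    return s / (1.0 - TEF_FRACTION)


def weekly_accelerometer_tee(
    daily_device_ee: Sequence[float],
    nonwear: Sequence[Sequence[NonWearEpisode]],
    sleep_hours: Sequence[float],
    participant: Participant,
    table: Optional[BmrReferenceTable] = None,
) -> float:
    """7-day mean TEE from the worn accelerometer plus imputed periods.

    Per day: device EE + imputed non-wear activity energy + BMR x
    sleep/24; the returned TEE/day is the mean over the 7 days.
    """
    device = np.asarray(daily_device_ee, dtype=float)
    sleep = np.asarray(sleep_hours, dtype=float)
    if device.shape != (7,) or sleep.shape != (7,) or len(nonwear) != 7:
        raise DomainError("expected exactly 7 days of device, episode and sleep data")
    bmr = basal_metabolic_rate(participant, table)
    totals = []
    for d in range(7):
        total = device[d] + bmr * sleep[d] / 24.0
        for episode in nonwear[d]:
            total += activity_energy(
                episode.met, episode.duration, participant.weight
            )
        totals.append(total)
    return float(np.mean(totals))


def mvpa_hours(
    profile: ActivityProfile, mets: MetSet, threshold: float = 3.0
) -> float:
    """Weekly hours of moderate-to-vigorous activity (MET >= threshold).

    Only the seven reported categories count; residual light time and
    sleep (1.0 MET) never qualify.  The threshold is inclusive, so a
    3.0-MET category (midrange "moderate") is MVPA while the calibrated
    2.4-MET value for the same category is not.
    """
    weekly = profile.weekly_hours()
    mask = mets.as_array()[:7] >= threshold
    return float(weekly[mask].sum())


def exercise_volume(
    profile: ActivityProfile, mets: MetSet, threshold: float = 3.0
) -> float:
    """Exercise volume (Ex = MET x hour) per week above the MVPA threshold."""
    weekly = profile.weekly_hours()
    met7 = mets.as_array()[:7]
    mask = met7 >= threshold
    return float((weekly[mask] * met7[mask]).sum())
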