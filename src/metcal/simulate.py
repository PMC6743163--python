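"""Seeded synthetic cohorts with the validation- and baseline-study
data structure.

Two generators:

* :func:`generate_validation_cohort` — small paired cohorts (default
  n = 31) in which the accelerometer TEE is constructed as the
  questionnaire TEE under a *known* true MET set plus additive Gaussian
  device noise.  Used for MET-recovery experiments where the truth is
  known by construction.
* :func:`generate_baseline_roster` — large age-stratified rosters (five
  groups, 25-69 years) with group-specific activity marginals and
  exclusion flags, for the cohort-trend analyses.

Marginals are truncated normals (activity times truncated at zero,
mirroring reported means/SDs of non-negative variables) with an optional
point mass at zero for the rarely-reported exercise categories whose
published medians are zero.  Weekly time budgets are enforced by
proportional shrinkage of activity hours when sleep plus activity would
exceed 168 h.  Within-person category correlations are not modelled
beyond that budget constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .cohort import AGE_GROUPS, BaselineRecord, BaselineRoster
from .energy import (
    WEEK_HOURS,
    ActivityProfile,
    BmrReferenceTable,
    MetSet,
    Participant,
    ValidationRecord,
    questionnaire_tee,
)


class GeneratorConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MarginalSpec:
    """A truncated-normal marginal with an optional point mass at zero.

    ``mean``/``sd`` parameterise the underlying normal before truncation
    to [lower, upper]; with probability ``zero_prob`` the draw is
    replaced by 0.  :meth:`implied_mean` / :meth:`implied_sd` give the
    analytic moments of the resulting mixture, which are what the
    generated data can be checked against.
    """

    mean: float
    sd: float
    lower: float = 0.0
    upper: float = math.inf
    zero_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise GeneratorConfigurationError("sd must be >= 0")
        if not self.lower < self.upper:
            raise GeneratorConfigurationError("need lower < upper")
        if not 0.0 <= self.zero_prob <= 1.0:
            raise GeneratorConfigurationError("zero_prob must be in [0, 1]")
        if self.sd == 0 and not (self.lower <= self.mean <= self.upper):
            raise GeneratorConfigurationError(
                "degenerate marginal mean outside truncation bounds"
            )

    def _ab(self) -> tuple[float, float]:
        return (
            (self.lower - self.mean) / self.sd,
            (self.upper - self.mean) / self.sd,
        )

    def _trunc_moments(self) -> tuple[float, float]:
        if self.sd == 0:
            return self.mean, 0.0
        a, b = self._ab()
        m, v = truncnorm.stats(a, b, loc=self.mean, scale=self.sd, moments="mv")
        return float(m), float(v)

    def implied_mean(self) -> float:
        m, _ = self._trunc_moments()
        return (1.0 - self.zero_prob) * m

    def implied_sd(self) -> float:
        m, v = self._trunc_moments()
        second = (1.0 - self.zero_prob) * (v + m * m)
        mu = self.implied_mean()
        return math.sqrt(max(second - mu * mu, 0.0))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.zero_prob >= 1.0:
            return np.zeros(size)
        if self.sd == 0:
            values = np.full(size, float(self.mean))
        else:
            a, b = self._ab()
            values = truncnorm.rvs(
                a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
            )
        if self.zero_prob > 0.0:
            values = np.where(rng.random(size) < self.zero_prob, 0.0, values)
        return values


#: activity variable names in questionnaire order (hours/week)
ACTIVITY_VARS = (
    "sitting",
    "standing",
    "walking",
    "heavy_work",
    "moderate",
    "vigorous",
    "very_vigorous",
)

# Validation-cohort marginals (n = 31 calibration sample).  Off-duty
# exercise categories have published medians of zero, modelled as point
# masses at zero with the nonzero part's mean scaled to preserve the
# published overall mean (very vigorous activity was not reported at
# all; its occurrence defaults to zero but is configurable).
VALIDATION_MARGINALS: dict[str, MarginalSpec] = {
    "age": MarginalSpec(48.7, 11.0, 31.0, 70.0),
    "bmi": MarginalSpec(22.4, 3.2, 17.5, 31.0),
    "height": MarginalSpec(158.0, 5.5, 140.0, 180.0),
    "sleep": MarginalSpec(7.2, 0.6, 5.5, 8.5),
    "sitting": MarginalSpec(13.9, 12.9, 0.0, 56.0),
    "standing": MarginalSpec(12.1, 9.9, 0.0, 50.0),
    "walking": MarginalSpec(11.4, 10.6, 0.0, 45.0),
    "heavy_work": MarginalSpec(1.1, 2.2, 0.0, 12.0),
    "moderate": MarginalSpec(36.1 / 0.5 / 60.0, 72.9 / 60.0, 0.0, 6.0, zero_prob=0.5),
    "vigorous": MarginalSpec(7.4 / 0.2 / 60.0, 24.2 / 60.0, 0.0, 2.5, zero_prob=0.8),
    "very_vigorous": MarginalSpec(0.5, 0.25, 0.0, 2.0, zero_prob=1.0),
}

# Baseline-survey marginals per age group (five strata).  Group weights
# follow the published stratum sizes.
BASELINE_GROUP_NS = {
    "25-29": 490,
    "30-39": 13553,
    "40-49": 11547,
    "50-59": 5093,
    "60-69": 254,
}

_BASELINE_ROWS = {
    # group: (age mean, sd, lo, hi), bmi(mean, sd), sleep(mean, sd),
    #        sitting, standing, walking, heavy (mean, sd in h/wk),
    #        moderate, vigorous (mean, sd in min/wk)
    "25-29": ((27.4, 1.4, 25, 29), (20.3, 2.6), (6.3, 1.0),
              (7.9, 8.1), (15.9, 13.1), (13.7, 12.0), (2.5, 3.7),
              (25.1, 59.9), (4.3, 23.1)),
    "30-39": ((34.5, 2.8, 30, 39), (21.1, 2.8), (6.5, 1.0),
              (7.0, 7.4), (17.6, 14.0), (13.6, 12.6), (2.1, 3.5),
              (19.6, 56.0), (2.5, 19.1)),
    "40-49": ((44.2, 2.9, 40, 49), (22.2, 2.8), (6.4, 0.9),
              (8.2, 9.1), (17.0, 14.0), (12.5, 12.6), (1.7, 3.2),
              (20.6, 60.4), (1.9, 16.2)),
    "50-59": ((53.1, 2.6, 50, 59), (22.8, 2.8), (6.4, 0.9),
              (11.0, 11.7), (16.1, 14.1), (10.3, 11.9), (1.2, 2.8),
              (29.5, 71.7), (2.7, 20.7)),
    "60-69": ((61.8, 2.2, 60, 69), (22.7, 2.8), (6.5, 0.9),
              (13.6, 12.8), (11.8, 12.9), (7.8, 10.6), (0.8, 2.6),
              (41.0, 92.6), (1.9, 16.5)),
}

_MODERATE_ZERO_PROB = 0.6
_VIGOROUS_ZERO_PROB = 0.9


def _baseline_group_marginals() -> dict[str, dict[str, MarginalSpec]]:
    out: dict[str, dict[str, MarginalSpec]] = {}
    for group, row in _BASELINE_ROWS.items():
        (a_m, a_s, a_lo, a_hi), bmi, sleep, sit, stand, walk, heavy, mod, vig = row
        out[group] = {
            "age": MarginalSpec(a_m, a_s, a_lo, a_hi),
            "bmi": MarginalSpec(bmi[0], bmi[1], 15.0, 35.0),
            "height": MarginalSpec(158.0, 5.5, 140.0, 180.0),
            "sleep": MarginalSpec(sleep[0], sleep[1], 3.5, 10.0),
            "sitting": MarginalSpec(sit[0], sit[1], 0.0, 60.0),
            "standing": MarginalSpec(stand[0], stand[1], 0.0, 60.0),
            "walking": MarginalSpec(walk[0], walk[1], 0.0, 60.0),
            "heavy_work": MarginalSpec(heavy[0], heavy[1], 0.0, 20.0),
            "moderate": MarginalSpec(
                mod[0] / (1.0 - _MODERATE_ZERO_PROB) / 60.0,
                mod[1] / 60.0, 0.0, 8.0, zero_prob=_MODERATE_ZERO_PROB,
            ),
            "vigorous": MarginalSpec(
                vig[0] / (1.0 - _VIGOROUS_ZERO_PROB) / 60.0,
                vig[1] / 60.0, 0.0, 4.0, zero_prob=_VIGOROUS_ZERO_PROB,
            ),
            "very_vigorous": MarginalSpec(0.5, 0.25, 0.0, 2.0, zero_prob=1.0),
        }
    return out


BASELINE_GROUP_MARGINALS = _baseline_group_marginals()

#: baseline exclusion rates: pregnancy, missing anthropometry, missing
#: activity responses, as fractions of the surveyed population
BASELINE_EXCLUSION_RATES = (998 / 48618, 1416 / 48618, 15267 / 48618)


@dataclass
class GeneratorConfig:
    """Cohort-generator settings; see the classmethod defaults.

    ``marginals`` drive the validation generator; ``group_marginals`` +
    ``group_weights`` drive the baseline generator.  ``exclusion_counts``
    switches the baseline generator to fixture mode with exact,
    mutually exclusive flag counts (pregnancy, missing anthropometry,
    missing activity) instead of Bernoulli rates.
    """

    n: int
    seed: int = 0
    true_mets: MetSet = field(default_factory=MetSet.estimated)
    sigma_noise: float = 150.0  # kcal/day accelerometer residual SD
    device_bias: float = 0.0
    two_season_fraction: float = 9.0 / 31.0
    marginals: dict[str, MarginalSpec] = field(
        default_factory=lambda: dict(VALIDATION_MARGINALS)
    )
    group_marginals: Optional[dict[str, dict[str, MarginalSpec]]] = None
    group_weights: Optional[dict[str, float]] = None
    exclusion_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    exclusion_counts: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise GeneratorConfigurationError("n must be > 0")
        if self.sigma_noise < 0:
            raise GeneratorConfigurationError("sigma_noise must be >= 0")
        if not 0.0 <= self.two_season_fraction <= 1.0:
            raise GeneratorConfigurationError("two_season_fraction in [0, 1]")
        if any(not 0.0 <= r <= 1.0 for r in self.exclusion_rates) or sum(
            self.exclusion_rates
        ) >= 1.0:
            raise GeneratorConfigurationError(
                "exclusion rates must lie in [0, 1] and jointly below 1"
            )
        sleep = self.marginals.get("sleep")
        if sleep is not None and sleep.mean > 24.0:
            raise GeneratorConfigurationError("mean sleep above 24 h/day")
        if self.exclusion_counts is not None:
            if sum(self.exclusion_counts) > self.n:
                raise GeneratorConfigurationError(
                    "fixture exclusion counts exceed the roster size"
                )

    @classmethod
    def validation_default(cls, n: int = 31, seed: int = 0, **kwargs) -> "GeneratorConfig":
        """Calibration-sample conditions (n = 31, published marginals)."""
        return cls(n=n, seed=seed, **kwargs)

    @classmethod
    def baseline_default(cls, n: int, seed: int = 0, **kwargs) -> "GeneratorConfig":
        """Baseline-survey conditions: five age strata with published
        group marginals, stratum weights and exclusion rates."""
        kwargs.setdefault("group_marginals", BASELINE_GROUP_MARGINALS)
        kwargs.setdefault(
            "group_weights", {g: float(BASELINE_GROUP_NS[g]) for g in AGE_GROUPS}
        )
        kwargs.setdefault("exclusion_rates", BASELINE_EXCLUSION_RATES)
        return cls(n=n, seed=seed, **kwargs)


def _enforce_time_budget(
    sleep: np.ndarray, activity: np.ndarray
) -> np.ndarray:
    """Shrink activity rows proportionally where 7*sleep + sum(PA) > 168."""
    committed = 7.0 * sleep + activity.sum(axis=1)
    over = committed > WEEK_HOURS
    if over.any():
        budget = WEEK_HOURS - 7.0 * sleep[over]
        total = activity[over].sum(axis=1)
        scale = np.where(total > 0, np.minimum(1.0, budget / total), 1.0)
        activity[over] *= scale[:, None]
    return activity


def _draw_people(
    rng: np.random.Generator,
    marginals: dict[str, MarginalSpec],
    n: int,
) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    cols["age"] = np.rint(marginals["age"].draw(rng, n)).astype(int)
    cols["height"] = marginals["height"].draw(rng, n)
    cols["bmi"] = marginals["bmi"].draw(rng, n)
    cols["weight"] = cols["bmi"] * (cols["height"] / 100.0) ** 2
    cols["sleep"] = marginals["sleep"].draw(rng, n)
    activity = np.column_stack(
        [marginals[v].draw(rng, n) for v in ACTIVITY_VARS]
    )
    cols["activity"] = _enforce_time_budget(cols["sleep"], activity)
    return cols


def _profile_from_row(sleep: float, activity: np.ndarray) -> ActivityProfile:
    return ActivityProfile(
        sleep_hours_per_day=float(sleep),
        work_hours=tuple(float(v) for v in activity[:4]),
        offduty_hours=tuple(float(v) for v in activity[4:]),
    )


def generate_validation_cohort(config: GeneratorConfig) -> list[ValidationRecord]:
    """Paired validation cohort with known true METs.

    ``accelerometer_tee = questionnaire_tee(true_mets) + bias + noise``;
    two-season participants get the average of two independent noise
    draws (their published TEE was a two-season mean).  Identical seed,
    identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    table = BmrReferenceTable.default()
    cols = _draw_people(rng, config.marginals, config.n)
    noise_a = rng.normal(0.0, config.sigma_noise, config.n) if config.sigma_noise > 0 else np.zeros(config.n)
    noise_b = rng.normal(0.0, config.sigma_noise, config.n) if config.sigma_noise > 0 else np.zeros(config.n)
    two_season = rng.random(config.n) < config.two_season_fraction
    noise = np.where(two_season, (noise_a + noise_b) / 2.0, noise_a)

    records = []
    for j in range(config.n):
        participant = Participant(
            id=f"v{j + 1:04d}",
            age=int(cols["age"][j]),
            weight=float(cols["weight"][j]),
            height=float(cols["height"][j]),
        )
        profile = _profile_from_row(cols["sleep"][j], cols["activity"][j])
        q = questionnaire_tee(participant, profile, config.true_mets, table)
        records.append(
            ValidationRecord(
                participant=participant,
                profile=profile,
                accelerometer_tee=float(q + config.device_bias + noise[j]),
            )
        )
    return records


def generate_baseline_roster(config: GeneratorConfig) -> BaselineRoster:
    """Age-stratified baseline roster with exclusion flags.

    Records are allocated to the five age groups with probabilities
    proportional to ``group_weights``; activity variables come from the
    group-specific marginals.  Flags are independent Bernoulli draws at
    ``exclusion_rates`` (pregnancy, missing anthropometry, missing
    activity) or exact mutually-exclusive counts in fixture mode.
    """
    if config.group_marginals is None:
        raise GeneratorConfigurationError(
            "baseline generation needs per-age-group marginals"
        )
    rng = np.random.default_rng(config.seed)
    groups = [g for g in AGE_GROUPS if g in config.group_marginals]
    weights = np.array(
        [
            (config.group_weights or {}).get(g, 1.0)
            for g in groups
        ],
        dtype=float,
    )
    probs = weights / weights.sum()
    gidx = rng.choice(len(groups), size=config.n, p=probs)

    # exclusion flags
    n = config.n
    if config.exclusion_counts is not None:
        c1, c2, c3 = config.exclusion_counts
        kinds = np.zeros(n, dtype=int)  # 0 retained, 1..3 excluded
        kinds[:c1] = 1
        kinds[c1 : c1 + c2] = 2
        kinds[c1 + c2 : c1 + c2 + c3] = 3
        rng.shuffle(kinds)
        pregnant = kinds == 1
        missing_anthro = kinds == 2
        missing_activity = kinds == 3
    else:
        r1, r2, r3 = config.exclusion_rates
        pregnant = rng.random(n) < r1
        missing_anthro = rng.random(n) < r2
        missing_activity = rng.random(n) < r3

    records: list[BaselineRecord] = [None] * n  # type: ignore[list-item]
    for gi, group in enumerate(groups):
        members = np.flatnonzero(gidx == gi)
        if members.size == 0:
            continue
        cols = _draw_people(rng, config.group_marginals[group], members.size)
        for local, j in enumerate(members):
            has_anthro = not missing_anthro[j]
            has_activity = not missing_activity[j]
            participant = Participant(
                id=f"b{j + 1:06d}",
                age=int(cols["age"][local]),
                weight=float(cols["weight"][local]) if has_anthro else None,
                height=float(cols["height"][local]) if has_anthro else None,
                pregnant=bool(pregnant[j]),
                has_anthropometry=has_anthro,
                has_activity_responses=has_activity,
            )
            profile = (
                _profile_from_row(cols["sleep"][local], cols["activity"][local])
                if has_activity
                else None
            )
            records[j] = BaselineRecord(participant=participant, profile=profile)
    return BaselineRoster(records=records)
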