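"""Baseline-cohort pipeline: exclusions, age groups, TEE/MVPA summaries
and ordered-group comparison tests.

Exclusion is sequential in a stated order (a record counts toward the
first criterion it trips), age groups are 25-29 then full decades to
60-69, and per-group TEE and MVPA are summarised under any MET set.
TEE differences across age groups use one-way ANOVA with Tukey HSD;
MVPA uses the Jonckheere-Terpstra ordered trend test and pairwise
Mann-Whitney with Bonferroni adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energy import (
    ActivityProfile,
    BmrReferenceTable,
    MetSet,
    Participant,
    mvpa_hours,
    questionnaire_tee,
)

AGE_GROUPS = ("25-29", "30-39", "40-49", "50-59", "60-69")
DEFAULT_EXCLUSION_ORDER = (
    "pregnancy",
    "missing_anthropometry",
    "missing_activity",
)


class BinningError(ValueError):
    """Age outside the study's 25-69 year range."""


class DegenerateVarianceError(ValueError):
    """All groups have zero within-group variance."""


class ConfigurationError(ValueError):
    pass


@dataclass
class BaselineRecord:
    """One baseline-survey participant with optional activity responses.

    ``profile`` is None when activity responses are missing.  Custom
    exclusion criteria (e.g. a missing sleep diary in the validation
    arm) can be attached via ``extra_flags``.
    """

    participant: Participant
    profile: Optional[ActivityProfile] = None
    extra_flags: dict[str, bool] = field(default_factory=dict)

    def flag(self, name: str) -> bool:
        if name == "pregnancy":
            return bool(self.participant.pregnant)
        if name == "missing_anthropometry":
            return not self.participant.has_anthropometry
        if name == "missing_activity":
            return not self.participant.has_activity_responses
        if name in self.extra_flags:
            return bool(self.extra_flags[name])
        raise KeyError(f"unknown exclusion flag {name!r}")


@dataclass
class BaselineRoster:
    records: list[BaselineRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ExclusionReport:
    """Sequential exclusion accounting; counts always conserve n_input."""

    n_input: int
    excluded: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input - sum(self.excluded.values()) != self.n_retained:
            raise ValueError("exclusion counts do not conserve the roster size")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "excluded": dict(self.excluded),
            "n_retained": self.n_retained,
        }


def apply_exclusions(
    roster: BaselineRoster,
    order: Sequence[str] = DEFAULT_EXCLUSION_ORDER,
) -> tuple[BaselineRoster, ExclusionReport]:
    """Filter a roster, attributing each record to the first tripped
    criterion in ``order``; returns (retained roster, report)."""
    counts = {name: 0 for name in order}
    retained: list[BaselineRecord] = []
    for rec in roster:
        for name in order:
            if rec.flag(name):
                counts[name] += 1
                break
        else:
            retained.append(rec)
    report = ExclusionReport(
        n_input=len(roster), excluded=counts, n_retained=len(retained)
    )
    return BaselineRoster(records=retained), report


def age_bin(age: int) -> str:
    """Age-group label: 25-29, then decades up to 60-69 (inclusive ends)."""
    age = int(age)
    if age < 25 or age > 69:
        raise BinningError(f"age {age} outside the 25-69 study range")
    if age <= 29:
        return "25-29"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


def _quantiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(q1), float(med), float(q3)


def group_summaries(
    roster: BaselineRoster,
    mets: MetSet,
    table: Optional[BmrReferenceTable] = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Per-age-group (and overall) n, mean/SD and median/IQR of TEE
    (kcal/day) and MVPA (h/week) under the given MET set."""
    tee = []
    mvpa = []
    groups = []
    for rec in roster:
        if rec.profile is None or not rec.participant.has_anthropometry:
            raise ConfigurationError(
                f"record {rec.participant.id!r} incomplete; apply exclusions first"
            )
        tee.append(questionnaire_tee(rec.participant, rec.profile, mets, table))
        mvpa.append(mvpa_hours(rec.profile, mets))
        groups.append(age_bin(rec.participant.age))
    tee_arr = np.asarray(tee)
    mvpa_arr = np.asarray(mvpa)
    groups_arr = np.asarray(groups)

    rows = []

    def _row(label: str, mask: np.ndarray) -> dict:
        t = tee_arr[mask]
        m = mvpa_arr[mask]
        t_q1, t_med, t_q3 = _quantiles(t)
        m_q1, m_med, m_q3 = _quantiles(m)
        return {
            "group": label,
            "n": int(mask.sum()),
            "mets": mets.label,
            "tee_mean": float(t.mean()),
            "tee_sd": float(t.std(ddof=1)) if len(t) > 1 else 0.0,
            "tee_median": t_med,
            "tee_q1": t_q1,
            "tee_q3": t_q3,
            "mvpa_mean": float(m.mean()),
            "mvpa_sd": float(m.std(ddof=1)) if len(m) > 1 else 0.0,
            "mvpa_median": m_med,
            "mvpa_q1": m_q1,
            "mvpa_q3": m_q3,
        }

    for g in AGE_GROUPS:
        mask = groups_arr == g
        if not mask.any():
            warnings.warn(f"age group {g} is empty; omitted", stacklevel=2)
            continue
        rows.append(_row(g, mask))
    if include_overall:
        rows.append(_row("all", np.ones(len(tee_arr), dtype=bool)))
    return pd.DataFrame(rows)


def grouped_values(
    roster: BaselineRoster,
    mets: MetSet,
    outcome: str = "mvpa",
    table: Optional[BmrReferenceTable] = None,
) -> tuple[list[str], list[np.ndarray]]:
    """Outcome ('tee' or 'mvpa') per record, split into the ordered age
    groups; returns (labels, samples) with empty groups omitted."""
    values = {g: [] for g in AGE_GROUPS}
    for rec in roster:
        if outcome == "tee":
            v = questionnaire_tee(rec.participant, rec.profile, mets, table)
        elif outcome == "mvpa":
            v = mvpa_hours(rec.profile, mets)
        else:
            raise ConfigurationError(f"unknown outcome {outcome!r}")
        values[age_bin(rec.participant.age)].append(v)
    labels = [g for g in AGE_GROUPS if values[g]]
    return labels, [np.asarray(values[g]) for g in labels]


def values_by_age_group(
    roster: BaselineRoster,
    mets: MetSet,
    outcome: str = "mvpa",
    table: Optional[BmrReferenceTable] = None,
) -> list[np.ndarray]:
    """Outcome per record split into the ordered age groups (samples only)."""
    return grouped_values(roster, mets, outcome, table)[1]


def _mw_count(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney count: #(x < y) + 0.5 #(x = y), via midranks."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    n_y = len(y)
    return float(ranks[len(x):].sum() - n_y * (n_y + 1) / 2.0)


def jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """Jonckheere-Terpstra statistic: summed MW counts over ordered pairs."""
    u = 0.0
    for i, j in combinations(range(len(groups)), 2):
        u += _mw_count(np.asarray(groups[i], float), np.asarray(groups[j], float))
    return u


@dataclass
class JTResult:
    statistic: float
    null_mean: float
    null_var: float
    z: float
    p: float
    method: str


def _jt_null_moments(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    sizes = np.array([len(g) for g in groups], dtype=float)
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    big_n = float(len(pooled))
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (big_n**2 - (sizes**2).sum()) / 4.0
    a = (
        big_n * (big_n - 1) * (2 * big_n + 5)
        - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    )
    b = (sizes * (sizes - 1) * (sizes - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
    c = (sizes * (sizes - 1)).sum() * (t * (t - 1)).sum()
    var = (
        a / 72.0
        + b / (36.0 * big_n * (big_n - 1) * (big_n - 2))
        + c / (8.0 * big_n * (big_n - 1))
    )
    return mean, var


def _jt_exact_p(groups: Sequence[np.ndarray], observed: float, mean: float) -> float:
    """Exact two-sided p by enumerating all group assignments of the pooled
    values (multinomial permutations); feasible for total n <= ~12."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    dev = abs(observed - mean) - 1e-9
    total = 0
    extreme = 0

    def recurse(indices: tuple[int, ...], gi: int, assigned: list[np.ndarray]):
        nonlocal total, extreme
        if gi == len(sizes) - 1:
            assigned_full = assigned + [pooled[list(indices)]]
            u = jt_statistic(assigned_full)
            total += 1
            if abs(u - mean) >= dev:
                extreme += 1
            return
        for combo in combinations(range(len(indices)), sizes[gi]):
            chosen = [indices[c] for c in combo]
            rest = tuple(
                indices[c] for c in range(len(indices)) if c not in set(combo)
            )
            recurse(rest, gi + 1, assigned + [pooled[chosen]])

    recurse(tuple(range(len(pooled))), 0, [])
    return extreme / total


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]], method: str = "auto"
) -> JTResult:
    """Two-sided Jonckheere-Terpstra trend test across ordered groups.

    Normal approximation with tie-corrected variance; ``method='exact'``
    (or 'auto' with total n <= 12) enumerates all permutations.
    """
    if len(groups) < 3:
        raise ConfigurationError("the trend test needs at least 3 ordered groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ConfigurationError("every group must be non-empty")
    u = jt_statistic(arrays)
    mean, var = _jt_null_moments(arrays)
    total_n = sum(len(a) for a in arrays)
    if method == "auto":
        method = "exact" if total_n <= 12 else "asymptotic"
    if method == "exact":
        if total_n > 14:
            raise ConfigurationError("exact enumeration limited to n <= 14")
        p = _jt_exact_p(arrays, u, mean)
        z = (u - mean) / math.sqrt(var) if var > 0 else 0.0
    elif method == "asymptotic":
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (u - mean) / math.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    return JTResult(
        statistic=float(u),
        null_mean=float(mean),
        null_var=float(var),
        z=float(z),
        p=float(p),
        method=method,
    )


def anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F and p plus Tukey HSD adjusted pairwise p-values."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ConfigurationError("ANOVA needs >= 2 groups with n >= 2 each")
    if all(a.var() == 0.0 for a in arrays):
        raise DegenerateVarianceError("zero within-group variance in every group")
    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(arrays))]
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
            }
        )
    return float(f_stat), float(p), pd.DataFrame(rows)


def pairwise_mannwhitney_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """All-pairs two-sided Mann-Whitney U with Bonferroni adjustment.

    p-values are multiplied by the number of comparisons C(k, 2) and
    capped at 1.  Small tie-free pairs use the exact distribution
    (scipy's 'auto'), larger ones the tie-corrected normal approximation.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ConfigurationError("need at least 2 groups")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(arrays))]
    m = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        res = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "u": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adj": float(min(1.0, res.pvalue * m)),
            }
        )
    return pd.DataFrame(rows)
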