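"""Method agreement between questionnaire TEE and accelerometer TEE.

Paired mean/SD difference, percentage difference, Bland-Altman bias and
95% limits of agreement, and the two-way mixed-effects absolute-agreement
single-measurement intraclass correlation ICC(2,1) with an F-based 95%
confidence interval (McGraw & Wong variance-components formulas).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energy import DomainError


class SampleSizeError(ValueError):
    """Too few pairs for the requested statistic."""


class DegenerateVarianceWarning(UserWarning):
    """Between-subject variance is (near) zero; the ICC is unstable."""


@dataclass(frozen=True)
class PairedTee:
    """One participant's questionnaire TEE and accelerometer TEE (kcal/day)."""

    id: str
    questionnaire_tee: float
    accelerometer_tee: float

    def __post_init__(self) -> None:
        if self.questionnaire_tee <= 0 or self.accelerometer_tee <= 0:
            raise DomainError(f"pair {self.id!r}: TEE values must be > 0")


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    table: pd.DataFrame  # columns: id, mean, difference


@dataclass
class AgreementReport:
    mean_difference: float
    sd_difference: float
    percentage_difference: float
    bland_altman: BlandAltman
    icc: float
    icc_ci_low: float
    icc_ci_high: float

    def to_dict(self) -> dict:
        return {
            "mean_difference_kcal": self.mean_difference,
            "sd_difference_kcal": self.sd_difference,
            "percentage_difference": self.percentage_difference,
            "bland_altman": {
                "bias_kcal": self.bland_altman.bias,
                "loa_low_kcal": self.bland_altman.loa_low,
                "loa_high_kcal": self.bland_altman.loa_high,
                "pairs": self.bland_altman.table.to_dict(orient="records"),
            },
            "icc": {
                "estimate": self.icc,
                "ci_low": self.icc_ci_low,
                "ci_high": self.icc_ci_high,
            },
        }


def _columns(pairs: Sequence[PairedTee]) -> tuple[np.ndarray, np.ndarray]:
    q = np.array([p.questionnaire_tee for p in pairs], dtype=float)
    a = np.array([p.accelerometer_tee for p in pairs], dtype=float)
    return q, a


def paired_differences(
    pairs: Sequence[PairedTee], per_pair: bool = False
) -> tuple[float, float, float]:
    """Mean and SD of (questionnaire - accelerometer) and the % difference.

    The percentage difference is computed on cohort means,
    ``(mean(Q) - mean(A)) / mean(A) x 100``; ``per_pair`` switches to the
    mean of per-pair percentage differences instead.
    """
    if len(pairs) < 2:
        raise SampleSizeError("paired differences need at least 2 pairs")
    q, a = _columns(pairs)
    d = q - a
    if per_pair:
        pct = float(np.mean(d / a) * 100.0)
    else:
        pct = float((q.mean() - a.mean()) / a.mean() * 100.0)
    return float(d.mean()), float(d.std(ddof=1)), pct


def bland_altman(pairs: Sequence[PairedTee]) -> BlandAltman:
    """Bias, 95% limits of agreement, and the per-pair plot table."""
    if len(pairs) < 3:
        raise SampleSizeError("Bland-Altman needs at least 3 pairs")
    q, a = _columns(pairs)
    d = q - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    table = pd.DataFrame(
        {
            "id": [p.id for p in pairs],
            "mean": (q + a) / 2.0,
            "difference": d,
        }
    )
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        table=table,
    )


def icc(pairs: Sequence[PairedTee]) -> tuple[float, float, float]:
    """ICC(2,1): two-way, absolute agreement, single measurement.

    Estimate from the paired-ANOVA mean squares and 95% CI via the
    McGraw & Wong F-distribution formulas.  Perfectly agreeing pairs
    return (1, 1, 1); near-zero between-subject variance triggers a
    :class:`DegenerateVarianceWarning`.
    """
    if len(pairs) < 5:
        raise SampleSizeError("ICC needs at least 5 pairs")
    q, a = _columns(pairs)
    if np.array_equal(q, a) and np.ptp(q) > 0:
        return 1.0, 1.0, 1.0  # perfect agreement with between-subject spread
    data = np.column_stack([q, a])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((data - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        # all values identical everywhere: no variance to apportion
        warnings.warn("no variance in either column", DegenerateVarianceWarning)
        return 1.0, 1.0, 1.0
    estimate = (msr - mse) / denom
    if mse == 0.0 and msc == 0.0:
        return 1.0, 1.0, 1.0
    if msr <= mse * (1.0 + 1e-12):
        warnings.warn(
            "between-subject variance is not above residual variance; "
            "the ICC estimate is unstable",
            DegenerateVarianceWarning,
        )

    icc_ = estimate
    alpha = 0.05
    if icc_ >= 1.0 or n * (1.0 - icc_) == 0.0:
        return float(estimate), float(estimate), float(estimate)
    a_ = (k * icc_) / (n * (1.0 - icc_))
    b_ = 1.0 + (k * icc_ * (n - 1.0)) / (n * (1.0 - icc_))
    v = (a_ * msc + b_ * mse) ** 2 / (
        (a_ * msc) ** 2 / (k - 1.0)
        + (b_ * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    ci_low = (
        n * (msr - f_low * mse)
        / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    ci_high = (
        n * (f_up * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    )
    return float(estimate), float(ci_low), float(ci_high)


def compute_agreement(pairs: Sequence[PairedTee]) -> AgreementReport:
    """Full agreement panel for one questionnaire-vs-accelerometer contrast."""
    mean_d, sd_d, pct = paired_differences(pairs)
    ba = bland_altman(pairs)
    est, lo, hi = icc(pairs)
    return AgreementReport(
        mean_difference=mean_d,
        sd_difference=sd_d,
        percentage_difference=pct,
        bland_altman=ba,
        icc=est,
        icc_ci_low=lo,
        icc_ci_high=hi,
    )
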