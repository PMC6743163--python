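"""Bayesian calibration of the eight questionnaire MET intensities.

Observation model: each validation participant's accelerometer TEE is
Normal(questionnaire TEE, sigma^2), i.i.d. across participants, with the
questionnaire TEE a known linear function of the eight unknown METs
(given anthropometry, sleep and reported hours).  Right-skewed gamma
priors centred on the midrange intensities keep the METs positive; the
questionnaire's anchor ranges can optionally be imposed as hard
truncation.  The residual scale sigma (kcal/day) gets a weakly
informative half-normal prior and is sampled unless fixed.

Sampling is componentwise random-walk Metropolis on the log scale with
Robbins-Monro-style batch adaptation of the proposal scales during
burn-in only (target acceptance 0.44); the kept chain is a fixed-kernel
Markov chain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .energy import (
    CATEGORIES,
    CATEGORY_BOUNDS,
    MIDRANGE_METS,
    BmrReferenceTable,
    MetSet,
    ValidationRecord,
    basal_metabolic_rate,
    questionnaire_tee,
    residual_light_hours,
)

PARAM_NAMES = tuple(f"met_{c}" for c in CATEGORIES) + ("sigma",)

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ConfigurationError(ValueError):
    """Invalid sampler configuration or unusable data."""


class PriorDominatedWarning(UserWarning):
    """A MET parameter has no activity time in the data (prior-only)."""


@dataclass
class PriorSpec:
    """Gamma priors for the eight METs and a half-normal prior for sigma.

    ``shape``/``rate`` are per-category gamma hyperparameters.  With
    ``truncate`` the questionnaire anchor ranges ``bounds`` become hard
    support constraints [L, U).  ``sigma_fixed`` freezes the residual SD
    instead of sampling it.
    """

    shape: np.ndarray
    rate: np.ndarray
    truncate: bool = False
    bounds: tuple[tuple[float, float], ...] = CATEGORY_BOUNDS
    sigma_prior_scale: float = 300.0
    sigma_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        self.shape = np.asarray(self.shape, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.shape.shape != (8,) or self.rate.shape != (8,):
            raise ConfigurationError("priors need 8 shape and 8 rate values")
        if np.any(self.shape <= 0) or np.any(self.rate <= 0):
            raise ConfigurationError("gamma shape and rate must be > 0")
        if self.truncate and any(lo >= hi for lo, hi in self.bounds):
            raise ConfigurationError("truncation bounds must satisfy L < U")
        if self.sigma_prior_scale <= 0:
            raise ConfigurationError("sigma prior scale must be > 0")
        if self.sigma_fixed is not None and self.sigma_fixed <= 0:
            raise ConfigurationError("fixed sigma must be > 0")

    @classmethod
    def default(
        cls,
        prior_mean: Sequence[float] = MIDRANGE_METS,
        shape: float = 4.0,
        truncate: bool = False,
        **kwargs,
    ) -> "PriorSpec":
        """Gamma priors with the given means and common shape.

        Shape 4 gives coefficient of variation 0.5: right-skewed and
        positive without dominating the likelihood.
        """
        shape_arr = np.full(8, float(shape))
        rate = shape_arr / np.asarray(prior_mean, dtype=float)
        return cls(shape=shape_arr, rate=rate, truncate=truncate, **kwargs)

    def prior_mean(self) -> np.ndarray:
        return self.shape / self.rate

    def _log_gamma_pdf_i(self, i: int, x: float) -> float:
        k, r = self.shape[i], self.rate[i]
        return k * math.log(r) - gammaln(k) + (k - 1.0) * math.log(x) - r * x

    def log_prior_met_i(self, i: int, x: float) -> float:
        """Unnormalised-under-truncation log prior for one MET."""
        if x <= 0:
            return -math.inf
        if self.truncate:
            lo, hi = self.bounds[i]
            if not (lo <= x < hi):
                return -math.inf
        return self._log_gamma_pdf_i(i, x)

    def log_prior_mets(self, mets: Sequence[float]) -> float:
        return sum(self.log_prior_met_i(i, float(m)) for i, m in enumerate(mets))

    def log_prior_sigma(self, sigma: float) -> float:
        if sigma <= 0:
            return -math.inf
        if self.sigma_fixed is not None:
            return 0.0
        s = self.sigma_prior_scale
        return (
            0.5 * math.log(2.0 / math.pi)
            - math.log(s)
            - sigma * sigma / (2.0 * s * s)
        )


@dataclass
class McmcConfig:
    """Chain length, seed, initial state and adaptation settings."""

    n_burnin: int = 1000
    n_keep: int = 10000
    seed: int = 0
    adapt_window: int = 50
    initial_mets: Optional[Sequence[float]] = None
    initial_sigma: float = 200.0
    proposal_scales: Optional[Sequence[float]] = None  # log-scale SDs, 9 values

    def __post_init__(self) -> None:
        if self.n_burnin <= 0 or self.n_keep <= 0:
            raise ConfigurationError("n_burnin and n_keep must be > 0")
        if self.adapt_window <= 0:
            raise ConfigurationError("adapt_window must be > 0")
        if self.initial_sigma <= 0:
            raise ConfigurationError("initial sigma must be > 0")
        if self.proposal_scales is not None:
            scales = np.asarray(self.proposal_scales, dtype=float)
            if scales.shape != (9,) or np.any(scales <= 0):
                raise ConfigurationError("need 9 positive proposal scales")


@dataclass
class Chain:
    """Kept posterior draws (n_keep x 9: MET1..8, sigma) plus run metadata."""

    draws: np.ndarray
    param_names: tuple[str, ...]
    acceptance_rates: np.ndarray
    config: McmcConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.param_names))

    def met_posterior_means(self) -> np.ndarray:
        return self.draws[:, :8].mean(axis=0)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, SD, 95% credible interval, effective
    sample size and Geweke convergence z-score."""

    table: pd.DataFrame

    def met_set(self, label: str = "estimated") -> MetSet:
        means = tuple(self.table["mean"].iloc[:8])
        return MetSet(met=means, label=label)

    def to_dict(self) -> dict:
        return {
            name: {k: float(v) for k, v in row.items()}
            for name, row in self.table.iterrows()
        }


def build_design(
    data: Sequence[ValidationRecord], table: Optional[BmrReferenceTable] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearise the questionnaire TEE: ``Q = offset + X @ mets``.

    ``X[j, i] = weight_j x 1.05 x PA_ij / 7 / 0.9`` (PA in h/week, PA8
    the residual) and ``offset_j = BMR_j x sleep_j / 24 / 0.9``; returns
    (X, offset, y) with y the accelerometer TEEs.
    """
    table = table or BmrReferenceTable.default()
    n = len(data)
    X = np.empty((n, 8))
    offset = np.empty(n)
    y = np.empty(n)
    for j, rec in enumerate(data):
        bmr = basal_metabolic_rate(rec.participant, table)
        weekly = np.append(
            rec.profile.weekly_hours(), residual_light_hours(rec.profile)
        )
        X[j] = rec.participant.weight * 1.05 * weekly / 7.0 / 0.9
        offset[j] = bmr * rec.profile.sleep_hours_per_day / 24.0 / 0.9
        y[j] = rec.accelerometer_tee
    return X, offset, y


def log_posterior(
    mets: Sequence[float],
    sigma: float,
    data: Sequence[ValidationRecord],
    priors: Optional[PriorSpec] = None,
    table: Optional[BmrReferenceTable] = None,
) -> float:
    """Log posterior density (up to a constant) at (mets, sigma).

    Reference implementation via :func:`questionnaire_tee` per record;
    the sampler uses the equivalent linearised design for speed.
    """
    if not data:
        raise ConfigurationError("log_posterior needs at least one record")
    priors = priors or PriorSpec.default()
    lp = priors.log_prior_mets(mets) + priors.log_prior_sigma(sigma)
    if not math.isfinite(lp):
        return -math.inf
    met_set = MetSet(met=tuple(float(m) for m in mets))
    for rec in data:
        q = questionnaire_tee(rec.participant, rec.profile, met_set, table)
        resid = rec.accelerometer_tee - q
        lp += (
            -_LOG_SQRT_2PI
            - math.log(sigma)
            - resid * resid / (2.0 * sigma * sigma)
        )
    return lp


def run_mcmc(
    data: Sequence[ValidationRecord],
    priors: Optional[PriorSpec] = None,
    config: Optional[McmcConfig] = None,
    table: Optional[BmrReferenceTable] = None,
) -> Chain:
    """Adaptive Metropolis-within-Gibbs over (MET1..8, sigma).

    Deterministic given (seed, config, data).  Categories with zero
    reported time in every record trigger a :class:`PriorDominatedWarning`
    (their MET is unidentifiable and follows its prior).
    """
    priors = priors or PriorSpec.default()
    config = config or McmcConfig()
    if len(data) < 2:
        raise ConfigurationError("MET calibration needs at least 2 records")
    X, offset, y = build_design(data, table)
    for i, cat in enumerate(CATEGORIES):
        if np.allclose(X[:, i], 0.0):
            warnings.warn(
                f"category {cat!r} has no reported activity time; its MET "
                "posterior is prior-dominated",
                PriorDominatedWarning,
                stacklevel=2,
            )

    rng = np.random.default_rng(config.seed)
    mets = np.asarray(
        config.initial_mets if config.initial_mets is not None else MIDRANGE_METS,
        dtype=float,
    ).copy()
    if priors.log_prior_mets(mets) == -math.inf:
        raise ConfigurationError("initial METs outside prior support")
    sample_sigma = priors.sigma_fixed is None
    sigma = float(priors.sigma_fixed if not sample_sigma else config.initial_sigma)

    log_scales = np.log(
        np.asarray(
            config.proposal_scales
            if config.proposal_scales is not None
            else np.full(9, 0.2),
            dtype=float,
        )
    )
    resid = y - offset - X @ mets
    ss = float(resid @ resid)
    n_obs = len(y)

    n_total = config.n_burnin + config.n_keep
    draws = np.empty((config.n_keep, 9))
    accepted = np.zeros(9)
    proposed = np.zeros(9)
    batch_acc = np.zeros(9)
    batch_prop = np.zeros(9)
    batch_index = 0
    lp_met = np.array(
        [priors.log_prior_met_i(i, mets[i]) for i in range(8)]
    )

    for it in range(n_total):
        in_burnin = it < config.n_burnin
        two_sigma_sq = 2.0 * sigma * sigma
        for i in range(8):
            prop = mets[i] * math.exp(
                math.exp(log_scales[i]) * rng.standard_normal()
            )
            proposed[i] += 1
            batch_prop[i] += 1
            lp_prop = priors.log_prior_met_i(i, prop)
            if lp_prop > -math.inf:
                resid_new = resid - X[:, i] * (prop - mets[i])
                ss_new = float(resid_new @ resid_new)
                log_alpha = (
                    (ss - ss_new) / two_sigma_sq
                    + lp_prop
                    - lp_met[i]
                    + math.log(prop)
                    - math.log(mets[i])
                )
                if math.log(rng.random()) < log_alpha:
                    mets[i] = prop
                    resid = resid_new
                    ss = ss_new
                    lp_met[i] = lp_prop
                    accepted[i] += 1
                    batch_acc[i] += 1
        if sample_sigma:
            prop = sigma * math.exp(
                math.exp(log_scales[8]) * rng.standard_normal()
            )
            proposed[8] += 1
            batch_prop[8] += 1
            log_alpha = (
                -n_obs * (math.log(prop) - math.log(sigma))
                - ss / (2.0 * prop * prop)
                + ss / (2.0 * sigma * sigma)
                + priors.log_prior_sigma(prop)
                - priors.log_prior_sigma(sigma)
                + math.log(prop)
                - math.log(sigma)
            )
            if math.log(rng.random()) < log_alpha:
                sigma = prop
                accepted[8] += 1
                batch_acc[8] += 1

        if in_burnin and (it + 1) % config.adapt_window == 0:
            batch_index += 1
            delta = min(0.1, 1.0 / math.sqrt(batch_index))
            with np.errstate(invalid="ignore"):
                rates = np.divide(
                    batch_acc,
                    np.maximum(batch_prop, 1.0),
                )
            log_scales += np.where(rates > 0.44, delta, -delta) * (
                batch_prop > 0
            )
            batch_acc[:] = 0.0
            batch_prop[:] = 0.0

        if not in_burnin:
            k = it - config.n_burnin
            draws[k, :8] = mets
            draws[k, 8] = sigma

    rates = accepted / np.maximum(proposed, 1.0)
    return Chain(
        draws=draws,
        param_names=PARAM_NAMES,
        acceptance_rates=rates,
        config=config,
    )


def _effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-pair autocorrelation sum (Geyer)."""
    n = len(x)
    x = x - x.mean()
    var0 = float(x @ x) / n
    if var0 == 0.0:
        return float(n)
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = rho[0]  # = 1
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n, max(1.0, n / tau)))


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """z-score comparing the mean of the first 10% vs the last 50%."""
    n = len(x)
    if np.ptp(x) == 0.0:
        return 0.0
    a = x[: max(1, int(first * n))]
    b = x[-max(1, int(last * n)) :]
    va = a.var(ddof=1) / len(a) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) / len(b) if len(b) > 1 else 0.0
    denom = math.sqrt(va + vb)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def summarize_posterior(chain: Chain) -> PosteriorSummary:
    """Posterior mean, SD, empirical 2.5/97.5 percentiles, ESS and Geweke z."""
    draws = chain.draws
    if draws.size == 0:
        raise ConfigurationError("cannot summarize an empty chain")
    rows = []
    for j, name in enumerate(chain.param_names):
        x = draws[:, j]
        q_lo, q_hi = np.percentile(x, [2.5, 97.5])
        rows.append(
            {
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                "q2.5": float(q_lo),
                "q97.5": float(q_hi),
                "ess": _effective_sample_size(x),
                "geweke_z": _geweke_z(x),
            }
        )
    table = pd.DataFrame(rows, index=list(chain.param_names))
    return PosteriorSummary(table=table)
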